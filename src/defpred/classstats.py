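"""Descriptive class-contrast statistics.

Two analyses compare the positive and negative class of a labeled
dataset: per-residue mean amino-acid composition with Mann-Whitney U
significance, and per-position residue enrichment at the sequence
termini (the counting matrix behind a two-sample logo).

The Mann-Whitney test uses exact enumeration of all class assignments
when the smaller class has at most 8 members (every C(n1+n2, n1)
assignment is scored), and the tie-corrected normal approximation
otherwise.  Positional enrichment uses Fisher's exact test per
(position, residue) 2x2 table, which is exact for count data where the
classic two-sample-logo t-test is only approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import encode_aac
from .seqio import NEGATIVE, POSITIVE, LabeledDataset
from .tables import ALPHABET

EXACT_MAX_N = 8


def mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for sample ``x`` against ``y`` (ties get half credit)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p-value by full enumeration.

    Enumerates every assignment of the pooled values into groups of sizes
    (n1, n2) and counts those whose U is at least as far from the null
    mean n1*n2/2 as the observed U.  Valid with ties (it is a permutation
    test on the actual values).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    # pairwise comparison matrix of pooled values: 1 if >, 0.5 if ==
    cmp = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    mu = n1 * n2 / 2.0
    obs = abs(mannwhitney_u(x, y) - mu)
    total = hits = 0
    idx = np.arange(n1 + n2)
    for group_a in combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(group_a)] = True
        u = cmp[mask][:, ~mask].sum()
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def mannwhitney_test(x, y) -> tuple[float, float]:
    """(U, two-sided p).  Exact enumeration when min(n1, n2) <= 8, else
    the tie-corrected normal approximation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    u = mannwhitney_u(x, y)
    if min(len(x), len(y)) <= EXACT_MAX_N:
        return u, exact_mannwhitney_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def compare_composition(ds: LabeledDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Per-residue class contrast of mean amino-acid composition.

    One row per residue: class means of AAC (percent), their difference
    (positive minus negative), the Mann-Whitney U of the positive class
    against the negative, the two-sided p-value and a significance flag
    at ``alpha`` (uncorrected).
    """
    pos = [p for p, l in ds.records if l == POSITIVE]
    neg = [p for p, l in ds.records if l == NEGATIVE]
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    aac_pos = np.stack([encode_aac(p) for p in pos])
    aac_neg = np.stack([encode_aac(p) for p in neg])
    rows = []
    for i, res in enumerate(ALPHABET):
        u, p = mannwhitney_test(aac_pos[:, i], aac_neg[:, i])
        m1, m2 = aac_pos[:, i].mean(), aac_neg[:, i].mean()
        rows.append({
            "residue": res,
            "mean_positive": m1,
            "mean_negative": m2,
            "difference": m1 - m2,
            "U": u,
            "p_value": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)


def positional_enrichment(
    ds: LabeledDataset,
    terminus: str = "N",
    depth: int = 10,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-position residue enrichment between classes at one terminus.

    Sequences shorter than ``depth`` are excluded.  The N-terminus reads
    positions 1..depth left to right; the C-terminus reads the last
    ``depth`` residues (position 1 = depth-th residue from the end).
    Each (position, residue) cell is tested with Fisher's exact test on
    the 2x2 table (residue r vs not-r) x (class); direction is the sign
    of the frequency difference (positive class minus negative).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    windows = {POSITIVE: [], NEGATIVE: []}
    for pep, label in ds.records:
        if len(pep) < depth:
            continue
        seg = pep.seq[:depth] if terminus == "N" else pep.seq[-depth:]
        windows[label].append(seg)
    n_pos, n_neg = len(windows[POSITIVE]), len(windows[NEGATIVE])
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"no sequences of length >= {depth} in one class")
    n_tests = depth * 20
    level = alpha / n_tests if bonferroni else alpha
    rows = []
    for pos_i in range(depth):
        col_pos = [s[pos_i] for s in windows[POSITIVE]]
        col_neg = [s[pos_i] for s in windows[NEGATIVE]]
        for res in ALPHABET:
            a = sum(c == res for c in col_pos)
            b = sum(c == res for c in col_neg)
            _, p = stats.fisher_exact([[a, n_pos - a], [b, n_neg - b]])
            diff = a / n_pos - b / n_neg
            rows.append({
                "terminus": terminus,
                "position": pos_i + 1,
                "residue": res,
                "count_positive": a,
                "count_negative": b,
                "freq_difference": diff,
                "p_value": float(p),
                "direction": "positive" if diff > 0 else ("negative" if diff < 0 else "none"),
                "significant": p < level,
            })
    return pd.DataFrame(rows)
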