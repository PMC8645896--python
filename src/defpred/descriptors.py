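"""Composition-based peptide descriptors.

Eight descriptor families over the 20-letter alphabet, each emitting a
named, ordered block of features:

========  =====================================================  ========
family    meaning                                                scale
========  =====================================================  ========
AAC       amino-acid composition (20)                            percent
DPC       overlapping dipeptide composition (400)                percent
TPC       overlapping tripeptide composition (8000)              percent
ATC       atom composition over C/H/N/O/S (5)                    fraction
BTC       bond composition: total/hydrogen/single/double (4)     per-residue mean
PCP       physicochemical-class composition (13)                 percent
CTD       composition / transition / distribution over three-    percent
          group partitions, 21 per attribute x 7 attributes
PAAC      Chou's pseudo-amino-acid composition, 20 + lambda      fraction
========  =====================================================  ========

The full default registry emits 8610 columns.  Column names and order are
fixed by :func:`feature_names` for a given :class:`EncoderConfig`; a
feature matrix produced under one config is only comparable to matrices
produced under the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Peptide
from .tables import (
    AA_INDEX,
    ALPHABET,
    PAAC_HYDROPHILICITY,
    PAAC_HYDROPHOBICITY,
    PAAC_SIDE_CHAIN_MASS,
    PCP_CLASSES,
    RESIDUE_ATOMS,
    RESIDUE_BONDS,
    load_ctd_groups,
)

REGISTRY_VERSION = "1.0"

DEFAULT_FAMILIES = ("AAC", "DPC", "TPC", "ATC", "BTC", "PCP", "CTD", "PAAC")

_ATOM_KINDS = ("C", "H", "N", "O", "S")
_BOND_KINDS = ("T", "H", "S", "D")
_DIST_BREAKS = ("00", "25", "50", "75", "100")

_CTD_GROUPS = load_ctd_groups()


@dataclass(frozen=True)
class EncoderConfig:
    """Which descriptor families to compute, and their parameters.

    ``paac_lambda`` is the number of sequence-order correlation tiers
    (every encoded peptide must be longer than it); ``paac_weight`` is
    Chou's weight ``w`` balancing composition against correlation.
    ``btc_raw_sum`` switches bond composition from the per-residue mean to
    the raw sum over the sequence.
    """

    families: tuple[str, ...] = DEFAULT_FAMILIES
    paac_lambda: int = 1
    paac_weight: float = 0.05
    ctd_properties: tuple[str, ...] = tuple(_CTD_GROUPS)
    btc_raw_sum: bool = False

    def __post_init__(self):
        unknown = set(self.families) - set(DEFAULT_FAMILIES)
        if unknown:
            raise ValueError(f"unknown descriptor families: {sorted(unknown)}")
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate families in config")
        if self.paac_lambda < 0:
            raise ValueError("paac_lambda must be >= 0")
        if self.paac_weight <= 0:
            raise ValueError("paac_weight must be > 0")
        bad = set(self.ctd_properties) - set(_CTD_GROUPS)
        if bad:
            raise ValueError(f"unknown CTD attributes: {sorted(bad)}")

    @property
    def min_length(self) -> int:
        """Shortest peptide the enabled families can encode."""
        need = 1
        if "DPC" in self.families:
            need = max(need, 2)
        if "TPC" in self.families:
            need = max(need, 3)
        if "PAAC" in self.families:
            need = max(need, self.paac_lambda + 1)
        return need

    def to_dict(self) -> dict:
        return {
            "families": list(self.families),
            "paac_lambda": self.paac_lambda,
            "paac_weight": self.paac_weight,
            "ctd_properties": list(self.ctd_properties),
            "btc_raw_sum": self.btc_raw_sum,
            "registry_version": REGISTRY_VERSION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(
            families=tuple(d["families"]),
            paac_lambda=int(d["paac_lambda"]),
            paac_weight=float(d["paac_weight"]),
            ctd_properties=tuple(d["ctd_properties"]),
            btc_raw_sum=bool(d.get("btc_raw_sum", False)),
        )


# --------------------------------------------------------------------------
# feature-name registry

def _family_names(family: str, cfg: EncoderConfig) -> list[str]:
    if family == "AAC":
        return [f"AAC_{a}" for a in ALPHABET]
    if family == "DPC":
        return [f"DPC_{a}{b}" for a in ALPHABET for b in ALPHABET]
    if family == "TPC":
        return [f"TPC_{a}{b}{c}" for a in ALPHABET for b in ALPHABET for c in ALPHABET]
    if family == "ATC":
        return [f"ATC_{k}" for k in _ATOM_KINDS]
    if family == "BTC":
        return [f"BTC_{k}" for k in _BOND_KINDS]
    if family == "PCP":
        return [f"PCP_{k}" for k in PCP_CLASSES]
    if family == "CTD":
        names = []
        for attr in cfg.ctd_properties:
            code = _CTD_GROUPS[attr]["code"]
            names += [f"CeTD_{code}{g}" for g in (1, 2, 3)]
            names += [f"CeTD_{code}_T{jk}" for jk in ("12", "13", "23")]
            for g in (1, 2, 3):
                names += [f"CeTD_{code}{g}_D{q}" for q in _DIST_BREAKS]
        return names
    if family == "PAAC":
        lam = cfg.paac_lambda
        names = [f"PAAC{lam}_{a}" for a in ALPHABET]
        names += [f"PAAC{lam}_theta{j}" for j in range(1, lam + 1)]
        return names
    raise ValueError(family)


def feature_names(cfg: EncoderConfig = EncoderConfig()) -> list[str]:
    """The full ordered column-name registry for a config."""
    out: list[str] = []
    for fam in cfg.families:
        out += _family_names(fam, cfg)
    return out


# --------------------------------------------------------------------------
# per-family encoders (each returns a 1-D float array in registry order)

def _codes(p: Peptide) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in p.seq), dtype=np.int64, count=len(p))


def encode_aac(p: Peptide) -> np.ndarray:
    """Percent composition of each residue; sums to 100."""
    counts = np.bincount(_codes(p), minlength=20).astype(float)
    return 100.0 * counts / len(p)


def encode_dpc(p: Peptide) -> np.ndarray:
    """Percent composition of the 400 overlapping dipeptides; sums to 100."""
    if len(p) < 2:
        raise ValueError(f"peptide {p.id!r}: DPC needs length >= 2")
    c = _codes(p)
    kmers = c[:-1] * 20 + c[1:]
    counts = np.bincount(kmers, minlength=400).astype(float)
    return 100.0 * counts / (len(p) - 1)


def encode_tpc(p: Peptide) -> np.ndarray:
    """Percent composition of the 8000 overlapping tripeptides; sums to 100."""
    if len(p) < 3:
        raise ValueError(f"peptide {p.id!r}: TPC needs length >= 3")
    c = _codes(p)
    kmers = (c[:-2] * 20 + c[1:-1]) * 20 + c[2:]
    counts = np.bincount(kmers, minlength=8000).astype(float)
    return 100.0 * counts / (len(p) - 2)


_ATOM_MATRIX = np.array(
    [[RESIDUE_ATOMS[a][k] for k in _ATOM_KINDS] for a in ALPHABET], dtype=float
)
_BOND_MATRIX = np.array(
    [[RESIDUE_BONDS[a][k] for k in _BOND_KINDS] for a in ALPHABET], dtype=float
)
_PCP_MATRIX = np.array(
    [[1.0 if a in members else 0.0 for a in ALPHABET] for members in PCP_CLASSES.values()]
)


def encode_atc(p: Peptide) -> np.ndarray:
    """Fraction of C/H/N/O/S atoms over all atoms in the chain; sums to 1."""
    counts = np.bincount(_codes(p), minlength=20).astype(float)
    atoms = counts @ _ATOM_MATRIX
    return atoms / atoms.sum()


def encode_btc(p: Peptide, raw_sum: bool = False) -> np.ndarray:
    """Bond composition: total / hydrogen / single / double bond counts,
    averaged per residue (or summed when ``raw_sum``)."""
    counts = np.bincount(_codes(p), minlength=20).astype(float)
    bonds = counts @ _BOND_MATRIX
    return bonds if raw_sum else bonds / len(p)


def encode_pcp(p: Peptide) -> np.ndarray:
    """Percent of residues falling in each physicochemical class."""
    counts = np.bincount(_codes(p), minlength=20).astype(float)
    return 100.0 * (_PCP_MATRIX @ counts) / len(p)


def _ctd_group_index(attr: str) -> np.ndarray:
    idx = np.empty(20, dtype=np.int64)
    for g, members in enumerate(_CTD_GROUPS[attr]["groups"]):
        for aa in members:
            idx[AA_INDEX[aa]] = g
    return idx


_CTD_INDEX = {attr: _ctd_group_index(attr) for attr in _CTD_GROUPS}


def encode_ctd(p: Peptide, cfg: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Composition, transition and distribution descriptors.

    Per attribute: 3 group compositions (percent of residues in each
    group), 3 transitions (percent of adjacent pairs crossing groups 1-2,
    1-3, 2-3 in either order, over L-1 pairs), and 5 distribution
    breakpoints per group (percent position along the chain of the first,
    25%, 50%, 75% and last residue of the group; all 0 when the group is
    absent).
    """
    c = _codes(p)
    L = len(p)
    out: list[float] = []
    for attr in cfg.ctd_properties:
        g = _CTD_INDEX[attr][c]
        # composition
        gcounts = np.bincount(g, minlength=3).astype(float)
        out += list(100.0 * gcounts / L)
        # transitions
        if L >= 2:
            a, b = g[:-1], g[1:]
            for j, k in ((0, 1), (0, 2), (1, 2)):
                n = np.sum(((a == j) & (b == k)) | ((a == k) & (b == j)))
                out.append(100.0 * n / (L - 1))
        else:
            out += [0.0, 0.0, 0.0]
        # distribution
        for grp in range(3):
            pos = np.flatnonzero(g == grp) + 1  # 1-based
            n = pos.size
            if n == 0:
                out += [0.0] * 5
                continue
            for q in (0, 25, 50, 75, 100):
                idx = 1 if q == 0 else math.ceil(q / 100.0 * n)
                out.append(100.0 * pos[idx - 1] / L)
    return np.array(out)


def _standardize_property(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[a] for a in ALPHABET])
    return (v - v.mean()) / v.std()  # population std over the 20 residues


_PAAC_PROPS = np.stack(
    [
        _standardize_property(PAAC_HYDROPHOBICITY),
        _standardize_property(PAAC_HYDROPHILICITY),
        _standardize_property(PAAC_SIDE_CHAIN_MASS),
    ]
)


def encode_paac(p: Peptide, cfg: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Chou's pseudo-amino-acid composition (20 + lambda components, sum 1).

    The first 20 components are residue frequencies discounted by the
    correlation mass; the last ``lambda`` are weighted tier correlations
    ``theta_j``, the mean squared difference of standardized properties
    between residues ``j`` apart.
    """
    lam, w = cfg.paac_lambda, cfg.paac_weight
    L = len(p)
    if L <= lam:
        raise ValueError(f"peptide {p.id!r}: PAAC needs length > lambda ({lam})")
    c = _codes(p)
    freqs = np.bincount(c, minlength=20).astype(float) / L
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = _PAAC_PROPS[:, c[j:]] - _PAAC_PROPS[:, c[:-j]]
        thetas[j - 1] = np.mean(diffs**2)  # mean over pairs and properties
    denom = 1.0 + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


# --------------------------------------------------------------------------
# batch encoding

_ENCODERS = {
    "AAC": lambda p, cfg: encode_aac(p),
    "DPC": lambda p, cfg: encode_dpc(p),
    "TPC": lambda p, cfg: encode_tpc(p),
    "ATC": lambda p, cfg: encode_atc(p),
    "BTC": lambda p, cfg: encode_btc(p, cfg.btc_raw_sum),
    "PCP": lambda p, cfg: encode_pcp(p),
    "CTD": lambda p, cfg: encode_ctd(p, cfg),
    "PAAC": lambda p, cfg: encode_paac(p, cfg),
}


def encode_peptide(p: Peptide, cfg: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """One peptide's full feature vector in registry order."""
    blocks = []
    for fam in cfg.families:
        try:
            blocks.append(_ENCODERS[fam](p, cfg))
        except ValueError as exc:
            raise ValueError(f"{fam} failed for peptide {p.id!r}: {exc}") from exc
    return np.concatenate(blocks)


def encode_all(
    records: Sequence[Peptide], cfg: EncoderConfig = EncoderConfig()
) -> pd.DataFrame:
    """Encode a batch of peptides into a peptides x features DataFrame.

    Rows are indexed by peptide id in input order; columns follow the
    registry for ``cfg``.  Deterministic: the same input always yields a
    bit-identical matrix.
    """
    names = feature_names(cfg)
    mat = np.empty((len(records), len(names)))
    for i, pep in enumerate(records):
        mat[i] = encode_peptide(pep, cfg)
    return pd.DataFrame(mat, index=[p.id for p in records], columns=names)


def write_feature_matrix(X: pd.DataFrame, path, cfg: EncoderConfig | None = None) -> None:
    """Serialize a feature matrix as TSV with a JSON config sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    X.to_csv(path, sep="\t", index_label="id")
    if cfg is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(cfg.to_dict(), indent=2))


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
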