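"""The three end-user services over a trained model bundle.

* Predict — score peptides and call defensin / non-defensin at a threshold.
* Scan — slide a window along a protein and score every subsequence, to
  localize defensin-like regions.
* Design — enumerate all single-residue substitution analogs of a parent
  peptide and rank them by score, to propose improved variants.

A *model bundle* couples a fitted classifier (with its scaler and ordered
feature contract) to the encoder configuration that produced its training
features, so that prediction-time featurization is guaranteed consistent
with training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .descriptors import EncoderConfig, encode_all
from .modeling import ModelSpec, TrainedModel, predict_scores
from .seqio import Peptide
from .tables import ALPHABET


@dataclass
class ModelBundle:
    """Everything needed to score new sequences: model + encoder config."""

    model: TrainedModel
    encoder: EncoderConfig
    metadata: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return self.model.threshold

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model.classifier, directory / "classifier.joblib")
        joblib.dump(self.model.scaler, directory / "scaler.joblib")
        meta = {
            "spec": {
                "kind": self.model.spec.kind,
                "params": dict(self.model.spec.params),
                "seed": self.model.spec.seed,
            },
            "feature_names": self.model.feature_names,
            "threshold": self.model.threshold,
            "encoder": self.encoder.to_dict(),
            "metadata": self.metadata,
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        spec = ModelSpec(
            meta["spec"]["kind"], meta["spec"]["params"], meta["spec"]["seed"]
        )
        model = TrainedModel(
            spec=spec,
            feature_names=list(meta["feature_names"]),
            scaler=joblib.load(directory / "scaler.joblib"),
            classifier=joblib.load(directory / "classifier.joblib"),
            threshold=float(meta["threshold"]),
        )
        return cls(model=model, encoder=EncoderConfig.from_dict(meta["encoder"]),
                   metadata=meta.get("metadata", {}))


@dataclass
class PredictionRecord:
    id: str
    sequence: str
    score: float
    label: str  # "defensin" / "non-defensin"


@dataclass
class ScanWindow:
    start: int  # 1-based, inclusive
    end: int
    sequence: str
    score: float
    label: str


@dataclass
class ScanResult:
    protein_id: str
    window: int
    windows: list[ScanWindow]


@dataclass
class DesignRecord:
    mutation: str  # e.g. "C5A"; "parent" for the reference row
    sequence: str
    score: float


@dataclass
class DesignResult:
    parent: Peptide
    parent_score: float
    analogs: list[DesignRecord]  # ranked by score descending


def _label(score: float, threshold: float) -> str:
    return "defensin" if score >= threshold else "non-defensin"


def _score_batch(bundle: ModelBundle, records: Sequence[Peptide]) -> np.ndarray:
    # scored one row at a time: BLAS matrix products can differ in the last
    # ulp between batch shapes, and the scan/design consistency contracts
    # (window score == standalone score) are exact, not approximate
    X = encode_all(records, bundle.encoder)[bundle.model.feature_names]
    return np.array(
        [predict_scores(bundle.model, X.iloc[[i]])[0] for i in range(len(X))]
    )


def predict(
    bundle: ModelBundle,
    records: Sequence[Peptide],
    threshold: float | None = None,
) -> tuple[list[PredictionRecord], list[tuple[str, str]]]:
    """Score each peptide and call its label at the threshold.

    Peptides that violate the encoder's preconditions (e.g. shorter than
    the minimum encodable length) are reported in the second return value
    as (id, reason) and the run continues.
    """
    thr = bundle.threshold if threshold is None else threshold
    ok, errors = [], []
    min_len = bundle.encoder.min_length
    for pep in records:
        if len(pep) < min_len:
            errors.append((pep.id, f"length {len(pep)} < encoder minimum {min_len}"))
        else:
            ok.append(pep)
    results = []
    if ok:
        scores = _score_batch(bundle, ok)
        for pep, s in zip(ok, scores):
            results.append(PredictionRecord(pep.id, pep.seq, float(s), _label(s, thr)))
    return results, errors


def scan(
    bundle: ModelBundle,
    protein: Peptide,
    window: int = 20,
    threshold: float | None = None,
    force: bool = False,
) -> ScanResult:
    """Score every length-``window`` subsequence of ``protein``.

    Each window's score is by contract identical to :func:`predict` run on
    that subsequence as a standalone peptide.  A window outside the
    model's trained length domain (10-60 by default) warns and requires
    ``force``.
    """
    import warnings

    L = len(protein)
    if window > L:
        raise ValueError(f"window {window} exceeds protein length {L}")
    lo, hi = bundle.metadata.get("length_domain", (10, 60))
    if not (lo <= window <= hi):
        if not force:
            raise ValueError(
                f"window {window} outside the model's trained length range "
                f"[{lo}, {hi}] (pass force=True to proceed)"
            )
        warnings.warn(f"window {window} outside trained length range [{lo}, {hi}]")
    thr = bundle.threshold if threshold is None else threshold
    subs = [
        Peptide(f"{protein.id}_w{i+1}", protein.seq[i:i + window])
        for i in range(L - window + 1)
    ]
    scores = _score_batch(bundle, subs)
    windows = [
        ScanWindow(i + 1, i + window, sub.seq, float(s), _label(s, thr))
        for i, (sub, s) in enumerate(zip(subs, scores))
    ]
    return ScanResult(protein_id=protein.id, window=window, windows=windows)


def design(
    bundle: ModelBundle,
    parent: Peptide,
    threshold: float | None = None,
) -> DesignResult:
    """Enumerate and rank all single-residue substitution analogs.

    Every position is mutated to each of the other 19 residues (19 x L
    analogs); analogs are sorted by score descending with ties broken by
    (position, substituted residue).  The parent's own score is returned
    as the reference.
    """
    L = len(parent)
    analogs: list[tuple[str, int, str, str]] = []  # (mutation, pos, new, seq)
    for i, orig in enumerate(parent.seq):
        for new in ALPHABET:
            if new == orig:
                continue
            seq = parent.seq[:i] + new + parent.seq[i + 1:]
            analogs.append((f"{orig}{i+1}{new}", i + 1, new, seq))
    peps = [parent] + [
        Peptide(f"{parent.id}_{mut}", seq) for mut, _, _, seq in analogs
    ]
    scores = _score_batch(bundle, peps)
    parent_score = float(scores[0])
    rows = [
        (mut, pos, new, seq, float(s))
        for (mut, pos, new, seq), s in zip(analogs, scores[1:])
    ]
    rows.sort(key=lambda r: (-r[4], r[1], r[2]))
    return DesignResult(
        parent=parent,
        parent_score=parent_score,
        analogs=[DesignRecord(mut, seq, s) for mut, _, _, seq, s in rows],
    )


def scan_table(result: ScanResult) -> pd.DataFrame:
    return pd.DataFrame(
        [(result.protein_id, w.start, w.end, w.sequence, w.score, w.label)
         for w in result.windows],
        columns=["id", "start", "end", "sequence", "score", "label"],
    )


def design_table(result: DesignResult) -> pd.DataFrame:
    rows = [("parent", result.parent.seq, result.parent_score)]
    rows += [(a.mutation, a.sequence, a.score) for a in result.analogs]
    return pd.DataFrame(rows, columns=["mutation", "sequence", "score"])
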