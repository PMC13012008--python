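"""Transcription-factor based NAPY subtype labeling (strict and relaxed rules).

Small cell lung cancer samples are assigned to one of four subtypes named
after the lineage transcription factor with the highest gene-wise z-scored
expression: NEUROD1 (N), ASCL1 (A), POU2F3 (P) or YAP1 (Y).

The *strict* rule additionally requires the top TF z-score to exceed the
second-best by at least a margin (default 0.3 z-units, inclusive) and to be
non-negative; samples failing either requirement stay unassigned
("borderline" cases).  The *relaxed* rule is a plain argmax with a
deterministic tie-break by the configured TF order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, MissingGeneError
from .expression import ExpressionMatrix, zscore_matrix

#: canonical TF gene -> subtype letter
TF_TO_LABEL = {"NEUROD1": "N", "ASCL1": "A", "POU2F3": "P", "YAP1": "Y"}
SUBTYPES = ("A", "N", "P", "Y")
UNASSIGNED = "unassigned"


@dataclass
class LabelingConfig:
    """Configuration of the TF labeling rules.

    ``tf_genes`` order doubles as the tie-break priority of the relaxed rule.
    """

    tf_genes: tuple[str, ...] = ("NEUROD1", "ASCL1", "POU2F3", "YAP1")
    margin: float = 0.3
    require_nonnegative_max: bool = True

    def __post_init__(self) -> None:
        if len(self.tf_genes) != 4 or len(set(self.tf_genes)) != 4:
            raise DomainError("tf_genes must be four distinct gene identifiers")
        if self.margin < 0:
            raise DomainError("margin must be >= 0")

    @property
    def labels(self) -> tuple[str, ...]:
        """Subtype letters in tf_genes order."""
        return tuple(TF_TO_LABEL.get(g, g[0]) for g in self.tf_genes)


@dataclass
class SubtypeCall:
    """One sample's subtype call with its provenance and TF z-scores."""

    sample_id: str
    label: str                      # A | N | P | Y | unassigned
    provenance: str                 # tf_strict | tf_relaxed | ml | consensus
    tf_zscores: dict[str, float] = field(default_factory=dict)
    tie_broken: bool = False


def _check_finite(z: np.ndarray) -> None:
    if not np.all(np.isfinite(z)):
        raise DomainError(f"non-finite TF z-scores: {z.tolist()}")


def assign_strict(z, cfg: LabelingConfig | None = None,
                  sample_id: str = "") -> SubtypeCall:
    """Strict rule: argmax TF iff (max - second max) >= margin and max >= 0.

    ``z`` is a sequence of four z-scores aligned to ``cfg.tf_genes``.
    Both comparisons are inclusive.
    """
    cfg = cfg or LabelingConfig()
    z = np.asarray(z, dtype=float)
    _check_finite(z)
    order = np.argsort(-z, kind="stable")
    top, second = z[order[0]], z[order[1]]
    ok = (top - second) >= cfg.margin
    if cfg.require_nonnegative_max:
        ok = ok and top >= 0.0
    label = cfg.labels[order[0]] if ok else UNASSIGNED
    return SubtypeCall(sample_id, label, "tf_strict",
                       dict(zip(cfg.tf_genes, z.tolist())))


def assign_relaxed(z, cfg: LabelingConfig | None = None,
                   sample_id: str = "") -> SubtypeCall:
    """Relaxed rule: argmax TF with ties broken by configured TF order."""
    cfg = cfg or LabelingConfig()
    z = np.asarray(z, dtype=float)
    _check_finite(z)
    best = int(np.argmax(z))  # first index on ties = configured order
    tie = bool(np.sum(z == z[best]) > 1)
    return SubtypeCall(sample_id, cfg.labels[best], "tf_relaxed",
                       dict(zip(cfg.tf_genes, z.tolist())), tie_broken=tie)


def label_cohort(m: ExpressionMatrix, cfg: LabelingConfig | None = None,
                 mode: str = "strict") -> list[SubtypeCall]:
    """Label every sample of a cohort: gene-wise z-scaling over the cohort
    passed in, then the per-sample strict or relaxed rule."""
    cfg = cfg or LabelingConfig()
    if mode not in ("strict", "relaxed"):
        raise DomainError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    missing = [g for g in cfg.tf_genes if g not in m.values.index]
    if missing:
        raise MissingGeneError(f"TF genes absent from matrix: {missing}")
    if m.n_samples < 2:
        raise InsufficientDataError("cohort labeling needs >= 2 samples")
    z = zscore_matrix(m).values.loc[list(cfg.tf_genes)]
    rule = assign_strict if mode == "strict" else assign_relaxed
    return [rule(z[s].to_numpy(), cfg, sample_id=s) for s in m.sample_ids]


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    """Tabular view of calls: sample_id, label, provenance, z<letter> columns."""
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "label": c.label,
               "provenance": c.provenance, "tie_broken": c.tie_broken}
        for tf, zv in c.tf_zscores.items():
            row[f"z{TF_TO_LABEL.get(tf, tf[0])}"] = zv
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def calls_to_series(calls: list[SubtypeCall]) -> pd.Series:
    """sample_id -> label Series."""
    return pd.Series({c.sample_id: c.label for c in calls}, name="label")
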