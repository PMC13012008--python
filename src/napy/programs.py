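"""Derivation of TF-associated downstream gene programs by exclusive correlation.

Each of the four NAPY transcription factors gets a k-gene (default 20)
downstream program: Pearson correlation of every gene with each TF is
computed over the training samples, each gene becomes a candidate only for
the TF it correlates with most strongly (*exclusive* association), and per
TF the top-k candidates by correlation are retained.  The four programs are
pairwise disjoint by construction and never contain the TF genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, MissingGeneError
from .expression import ExpressionMatrix


@dataclass
class DerivationConfig:
    k: int = 20
    exclude_genes: tuple[str, ...] | None = None  # defaults to the TF genes
    require_positive_corr: bool = True
    min_candidates_policy: str = "error"  # or "take_all_warn"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DomainError("k must be >= 1")
        if self.min_candidates_policy not in ("error", "take_all_warn"):
            raise DomainError(f"unknown policy {self.min_candidates_policy!r}")


@dataclass
class TFProgram:
    """Ordered downstream signature of one TF (descending correlation)."""

    tf: str
    genes: list[str]
    correlations: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise DomainError(f"duplicate genes in program for {self.tf}")
        if self.correlations and any(
            a < b for a, b in zip(self.correlations, self.correlations[1:])
        ):
            raise DomainError("correlations must be sorted non-increasing")


def correlate_to_tfs(m: ExpressionMatrix, tf_genes) -> pd.DataFrame:
    """Pearson r of every gene against each TF over samples (genes x TFs).

    Zero-variance genes get r = 0 against all TFs.
    """
    tf_genes = list(tf_genes)
    if m.n_samples < 3:
        raise InsufficientDataError("correlation needs >= 3 samples")
    missing = [g for g in tf_genes if g not in m.values.index]
    if missing:
        raise MissingGeneError(f"TF genes absent from matrix: {missing}")
    X = m.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    safe = np.where(norms == 0.0, 1.0, norms)
    Xn = Xc / safe[:, None]
    tf_idx = [m.values.index.get_loc(g) for g in tf_genes]
    R = Xn @ Xn[tf_idx].T
    R[norms == 0.0, :] = 0.0
    for j, i in enumerate(tf_idx):
        if norms[i] == 0.0:
            R[:, j] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    return pd.DataFrame(R, index=m.values.index, columns=tf_genes)


def select_programs(corr: pd.DataFrame, cfg: DerivationConfig | None = None) -> dict[str, TFProgram]:
    """Pick each TF's top-k exclusively-associated genes from a correlation table.

    A gene is a candidate only for its argmax-correlation TF (ties -> first
    TF in column order); candidates with non-positive best correlation are
    dropped when ``require_positive_corr``.  Within a TF, rank by descending
    r with lexicographic gene-ID tie-break.
    """
    cfg = cfg or DerivationConfig()
    tf_genes = list(corr.columns)
    exclude = set(cfg.exclude_genes) if cfg.exclude_genes is not None else set(tf_genes)
    cand = corr.drop(index=[g for g in exclude if g in corr.index])
    vals = cand.to_numpy(dtype=float)
    best_tf = vals.argmax(axis=1)  # first max on ties = column order
    best_r = vals[np.arange(len(cand)), best_tf]
    programs: dict[str, TFProgram] = {}
    for j, tf in enumerate(tf_genes):
        mask = best_tf == j
        if cfg.require_positive_corr:
            mask &= best_r > 0.0
        genes = cand.index[mask]
        rs = best_r[mask]
        order = sorted(range(len(genes)), key=lambda i: (-rs[i], genes[i]))
        if len(order) < cfg.k:
            msg = (f"TF {tf}: only {len(order)} candidate genes for a "
                   f"{cfg.k}-gene program")
            if cfg.min_candidates_policy == "error":
                raise InsufficientDataError(msg)
            warnings.warn(msg + "; taking all candidates", stacklevel=2)
        top = order[: cfg.k]
        programs[tf] = TFProgram(tf, [genes[i] for i in top],
                                 [float(rs[i]) for i in top])
    return programs


def derive_programs(m: ExpressionMatrix, tf_genes,
                    cfg: DerivationConfig | None = None) -> dict[str, TFProgram]:
    """Correlate then select: the full program-derivation step on one cohort."""
    return select_programs(correlate_to_tfs(m, tf_genes), cfg)


def programs_to_frame(programs: dict[str, TFProgram]) -> pd.DataFrame:
    rows = [
        {"tf": p.tf, "rank": i + 1, "gene": g,
         "r": p.correlations[i] if p.correlations else np.nan}
        for p in programs.values()
        for i, g in enumerate(p.genes)
    ]
    return pd.DataFrame(rows)


def program_feature_genes(programs: dict[str, TFProgram]) -> list[str]:
    """Concatenated feature list (TF order preserved, programs disjoint)."""
    out: list[str] = []
    for p in programs.values():
        out.extend(p.genes)
    if len(out) != len(set(out)):
        raise DomainError("programs are not pairwise disjoint")
    return out
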