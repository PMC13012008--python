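"""Signature-compendium scoring across subtypes with coherence filtering.

A gene signature is scored per sample as the mean gene-wise z-score of its
member genes.  Before any differential testing, signatures are filtered by
a *coherence score* — the mean pairwise Pearson correlation among the
signature's genes in the cohort — which must exceed 0.2 (configurable) for
the signature to be considered coherently expressed in the dataset.
Surviving signatures are tested for subtype differences with pairwise
two-sided Wilcoxon rank-sum tests (6 subtype pairs, Bonferroni-adjusted
within the signature); a signature is retained when at least three of the
six adjusted p values fall below alpha.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, CoverageError, DomainError, InsufficientDataError
from .expression import ExpressionMatrix
from .labeling import SUBTYPES


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise DomainError(f"signature {self.name!r} needs >= 2 genes")
        if len(self.genes) != len(set(self.genes)):
            raise DomainError(f"duplicate genes in signature {self.name!r}")


@dataclass
class SignatureResult:
    name: str
    scores: pd.Series
    coherence: float
    genes_used: int
    genes_total: int
    pairwise_tests: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    n_significant_pairs: int = 0
    retained: bool = False
    anova_f: float = float("nan")


def read_gmt(path) -> list[GeneSignature]:
    """Read gene sets from the tab-separated gene-set exchange dialect:
    name <tab> description <tab> gene1 <tab> gene2 ..."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ContractError(f"malformed gene-set record: {line[:80]!r}")
            sigs.append(GeneSignature(parts[0], parts[2:], source_tag=parts[1]))
    return sigs


def write_gmt(sigs: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, s.source_tag or "na", *s.genes]) + "\n")


def score_signature(z: ExpressionMatrix, sig: GeneSignature,
                    min_present: float = 0.5) -> pd.Series:
    """Per-sample mean z-score over the signature genes present in the matrix."""
    if z.scale_tag != "zscore":
        raise DomainError("score_signature expects a z-score matrix")
    present = [g for g in sig.genes if g in z.values.index]
    if len(present) < min_present * len(sig.genes):
        missing = sorted(set(sig.genes) - set(present))
        raise CoverageError(
            f"signature {sig.name!r}: only {len(present)}/{len(sig.genes)} genes "
            f"present (missing {missing})"
        )
    return z.values.loc[present].mean(axis=0).rename(sig.name)


def coherence_score(m: ExpressionMatrix, sig: GeneSignature) -> float:
    """Mean off-diagonal pairwise Pearson correlation among present genes."""
    present = [g for g in sig.genes if g in m.values.index]
    if len(present) < 2:
        raise CoverageError(f"signature {sig.name!r}: < 2 genes present")
    if m.n_samples < 3:
        raise InsufficientDataError("coherence needs >= 3 samples")
    X = m.values.loc[present].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    safe = np.where(norms == 0.0, 1.0, norms)
    R = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    R[norms == 0.0, :] = 0.0
    R[:, norms == 0.0] = 0.0
    n = len(present)
    off = (R.sum() - np.trace(R)) / (n * (n - 1))
    return float(off)


_PAIRS = list(itertools.combinations(SUBTYPES, 2))


def differential_by_subtype(scores: pd.Series, labels: pd.Series,
                            alpha: float = 0.05,
                            min_significant: int = 3) -> tuple[pd.DataFrame, int, bool]:
    """Pairwise two-sided Wilcoxon rank-sum tests across the 6 subtype pairs.

    Normal approximation with tie and continuity correction; Bonferroni
    adjustment multiplies raw p by 6 (capped at 1).  Returns
    (pairwise table, n significant adjusted pairs, retained flag).
    Pairs with a class below 2 samples are skipped and counted
    non-significant with a warning.
    """
    common = scores.index.intersection(labels.index)
    scores, labels = scores.loc[common], labels.loc[common]
    groups = {c: scores[labels == c].to_numpy() for c in SUBTYPES}
    n_classes = sum(len(v) >= 2 for v in groups.values())
    if n_classes < 2:
        raise InsufficientDataError("need >= 2 subtypes with >= 2 samples each")
    rows = []
    for a, b in _PAIRS:
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            warnings.warn(f"pair {a}-{b} skipped: class below 2 samples",
                          stacklevel=2)
            rows.append({"pair": f"{a}-{b}", "p_raw": np.nan, "p_adj": np.nan})
            continue
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        rows.append({"pair": f"{a}-{b}", "p_raw": p,
                     "p_adj": min(1.0, p * len(_PAIRS))})
    table = pd.DataFrame(rows)
    n_sig = int((table["p_adj"] < alpha).sum())
    return table, n_sig, n_sig >= min_significant


def select_representative(candidates: dict[str, pd.Series],
                          labels: pd.Series) -> str:
    """Among signatures describing one biological process, pick the one with
    the highest one-way ANOVA F across the four subtypes (ties -> name)."""
    if not candidates:
        raise ContractError("no candidate signatures")
    fvals = {}
    for name in sorted(candidates):
        fvals[name] = anova_f(candidates[name], labels)
    if all(not np.isfinite(v) for v in fvals.values()):
        raise DomainError("ANOVA F undefined for every candidate "
                          "(zero within-group variance)")
    return max(sorted(fvals), key=lambda n: (np.nan_to_num(fvals[n], nan=-np.inf)))


def anova_f(scores: pd.Series, labels: pd.Series) -> float:
    common = scores.index.intersection(labels.index)
    scores, labels = scores.loc[common], labels.loc[common]
    samples = [scores[labels == c].to_numpy() for c in SUBTYPES
               if (labels == c).sum() >= 2]
    if len(samples) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups with >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = stats.f_oneway(*samples).statistic
    return float(f)


def top_fraction_composition(scores: pd.Series, labels: pd.Series,
                             fraction: float = 0.05) -> pd.Series:
    """Subtype shares (percent, summing to 100) among the top-scoring samples.

    The top ``ceil(fraction * n)`` samples are taken; ties at the cutoff are
    broken by sample ID for determinism.
    """
    if not (0 < fraction < 1):
        raise ContractError("fraction must be in (0, 1)")
    common = scores.index.intersection(labels.index)
    n = len(common)
    if n < math.ceil(1.0 / fraction):
        raise ContractError(f"need >= {math.ceil(1.0 / fraction)} samples, got {n}")
    scores, labels = scores.loc[common], labels.loc[common]
    k = math.ceil(fraction * n)
    order = sorted(common, key=lambda s: (-scores[s], s))
    top = labels.loc[order[:k]]
    shares = top.value_counts().reindex(list(SUBTYPES), fill_value=0)
    return (100.0 * shares / k).rename("share_pct")


def analyze_compendium(m: ExpressionMatrix, z: ExpressionMatrix,
                       sigs: list[GeneSignature], labels: pd.Series,
                       coherence_min: float = 0.2, alpha: float = 0.05,
                       min_present: float = 0.5) -> list[SignatureResult]:
    """Coherence-filter, score, and differentially test a signature compendium.

    ``m`` is the log2(TPM+1) matrix (for coherence), ``z`` its gene-wise
    z-scored version (for scoring).  Signatures at or below the coherence
    threshold are returned unscored-for-significance with retained=False.
    """
    out = []
    for sig in sigs:
        try:
            coh = coherence_score(m, sig)
            scores = score_signature(z, sig, min_present=min_present)
        except CoverageError as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        used = sum(g in z.values.index for g in sig.genes)
        res = SignatureResult(sig.name, scores, coh, used, len(sig.genes))
        if coh > coherence_min:
            res.pairwise_tests, res.n_significant_pairs, res.retained = (
                differential_by_subtype(scores, labels, alpha=alpha))
            res.anova_f = anova_f(scores, labels)
        out.append(res)
    return out
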