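"""Alteration-frequency summaries and exact tests of alteration-subtype association.

Alteration calls arrive as long-format records (gene, sample, class) with
class in {snv, amplification, deletion}.  Per-gene frequencies use the
"any alteration" convention by default (a sample counts once however many
classes hit the gene); genes altered in more than 5% of the cohort are
retained for association testing.  Association with the four subtypes is
assessed with a two-sided Fisher exact test on the 2 x 4
altered/not-altered table, using the probability-mass criterion: the p
value sums the null (fixed-margins hypergeometric) probabilities of all
tables no more probable than the observed one.  Full enumeration is used
when feasible, otherwise seeded Monte Carlo sampling of fixed-margin
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ContractError, DomainError
from .labeling import SUBTYPES

ALTERATION_CLASSES = ("snv", "amplification", "deletion")


@dataclass
class FisherResult:
    p: float
    method: str                    # full_enumeration | monte_carlo
    n_tables: int = 0              # tables enumerated, or MC replicates
    seed: int | None = None


def validate_alterations(table: pd.DataFrame, universe) -> pd.DataFrame:
    """Check the (gene, sample, alteration_class) long table against a sample universe."""
    required = {"gene", "sample", "alteration_class"}
    if not required.issubset(table.columns):
        raise ContractError(f"alteration table needs columns {sorted(required)}")
    bad_class = set(table["alteration_class"]) - set(ALTERATION_CLASSES)
    if bad_class:
        raise ContractError(f"unknown alteration classes: {sorted(bad_class)}")
    unknown = set(table["sample"]) - set(universe)
    if unknown:
        raise ContractError(f"records reference unknown samples: {sorted(unknown)[:5]}")
    if table.duplicated(["gene", "sample", "alteration_class"]).any():
        raise ContractError("duplicate (gene, sample, class) records")
    return table


def alteration_frequencies(table: pd.DataFrame, labels: pd.Series,
                           min_freq: float = 0.05,
                           alteration_class: str | None = None) -> pd.DataFrame:
    """Per-gene overall and per-subtype alteration frequencies.

    A sample with several alteration classes in one gene counts once.
    Genes with overall frequency strictly greater than ``min_freq`` get
    ``retained=True``.
    """
    universe = labels.index
    if len(universe) == 0:
        raise ContractError("empty sample universe")
    validate_alterations(table, universe)
    if alteration_class is not None:
        table = table[table["alteration_class"] == alteration_class]
    if table.empty:
        warnings.warn("no alteration records after filtering", stacklevel=2)
        return pd.DataFrame(columns=["gene", "n_altered", "freq", "retained",
                                     *[f"freq_{c}" for c in SUBTYPES]])
    hits = table[["gene", "sample"]].drop_duplicates()
    n = len(universe)
    sizes = labels.value_counts()
    rows = []
    for gene, grp in hits.groupby("gene"):
        altered = set(grp["sample"])
        row = {"gene": gene, "n_altered": len(altered),
               "freq": len(altered) / n}
        for c in SUBTYPES:
            members = labels.index[labels == c]
            row[f"freq_{c}"] = (sum(s in altered for s in members) / sizes.get(c, np.nan)
                                if sizes.get(c, 0) else np.nan)
        row["retained"] = row["freq"] > min_freq
        rows.append(row)
    return pd.DataFrame(rows).sort_values("freq", ascending=False,
                                          ignore_index=True)


def _log_table_prob(table: np.ndarray, lgr: np.ndarray, lgc: np.ndarray,
                    lgn: float) -> float:
    """Log multivariate hypergeometric probability of a fixed-margins table."""
    return float(lgr.sum() + lgc.sum() - lgn - gammaln(table + 1).sum())


def _margins(t: np.ndarray):
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    return r, c, gammaln(r + 1), gammaln(c + 1), gammaln(t.sum() + 1)


def _enumerate_pvalue(t: np.ndarray, max_tables: int) -> FisherResult | None:
    """DFS over all tables with the observed margins; None if the bound trips."""
    r, c, lgr, lgc, lgn = _margins(t)
    obs_lp = _log_table_prob(t, lgr, lgc, lgn)
    tol = 1e-10 * abs(obs_lp) + 1e-12
    nrow, ncol = t.shape
    counter = {"n": 0}
    lg = gammaln(np.arange(int(t.sum()) + 2))

    def cell_logfact_sum(row):
        return sum(lg[v + 1] for v in row)

    total_lp: list[float] = []

    def rec(i: int, col_rem: np.ndarray, acc_logfact: float) -> bool:
        if i == nrow - 1:
            counter["n"] += 1
            if counter["n"] > max_tables:
                return False
            lp = lgr.sum() + lgc.sum() - lgn - (acc_logfact + cell_logfact_sum(col_rem))
            if lp <= obs_lp + tol:
                total_lp.append(lp)
            return True
        # enumerate row i over compositions of r[i] bounded by col_rem
        row = np.zeros(ncol, dtype=int)

        def fill(j: int, rem: int) -> bool:
            if j == ncol - 1:
                if rem > col_rem[j]:
                    return True
                row[j] = rem
                return rec(i + 1, col_rem - row,
                           acc_logfact + cell_logfact_sum(row))
            lo = max(0, rem - int(col_rem[j + 1:].sum()))
            hi = min(int(col_rem[j]), rem)
            for v in range(lo, hi + 1):
                row[j] = v
                if not fill(j + 1, rem - v):
                    return False
            row[j] = 0
            return True

        return fill(0, int(r[i]))

    if not rec(0, c.copy(), 0.0):
        return None
    # log-sum-exp for numerical stability
    lps = np.asarray(total_lp)
    mx = lps.max()
    p = float(np.exp(mx) * np.exp(lps - mx).sum())
    return FisherResult(min(1.0, p), "full_enumeration", counter["n"])


def fisher_exact_rxc(table, max_tables: int = 10_000_000,
                     mc_reps: int = 100_000, seed: int = 0) -> FisherResult:
    """Two-sided Fisher exact test on an r x c count table.

    The p value is the total null probability of tables (with the observed
    margins) whose probability does not exceed the observed table's.  Falls
    back to Monte Carlo sampling of fixed-margin tables when more than
    ``max_tables`` tables would need enumerating.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise DomainError("table must be 2-D")
    if (t < 0).any():
        raise DomainError("negative cell count")
    if t.sum() <= 0:
        raise DomainError("table total must be positive")
    r, c, lgr, lgc, lgn = _margins(t)
    # degenerate margins: only one table possible
    if (r > 0).sum() < 2 or (c > 0).sum() < 2:
        return FisherResult(1.0, "full_enumeration", 1)
    res = _enumerate_pvalue(t, max_tables)
    if res is not None:
        return res
    obs_lp = _log_table_prob(t, lgr, lgc, lgn)
    tol = 1e-10 * abs(obs_lp) + 1e-12
    rng = np.random.default_rng(seed)
    dist = stats.random_table(r, c)
    hits = 0
    chunk = 10_000
    done = 0
    while done < mc_reps:
        k = min(chunk, mc_reps - done)
        samples = dist.rvs(size=k, random_state=rng)
        lps = (lgr.sum() + lgc.sum() - lgn
               - gammaln(samples + 1).sum(axis=(1, 2)))
        hits += int((lps <= obs_lp + tol).sum())
        done += k
    p = (hits + 1) / (mc_reps + 1)
    return FisherResult(float(p), "monte_carlo", mc_reps, seed)


def associate_genes(table: pd.DataFrame, labels: pd.Series,
                    genes=None, alteration_class: str | None = None,
                    min_freq: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Fisher exact association of per-gene alteration status with subtype.

    Builds the 2 x 4 altered/not-altered-by-subtype table per retained gene
    (overall frequency > ``min_freq``) and reports the exact p value.
    """
    freqs = alteration_frequencies(table, labels, min_freq=min_freq,
                                   alteration_class=alteration_class)
    if genes is not None:
        freqs = freqs[freqs["gene"].isin(set(genes))]
    else:
        freqs = freqs[freqs["retained"]]
    if alteration_class is not None:
        table = table[table["alteration_class"] == alteration_class]
    hits = table[["gene", "sample"]].drop_duplicates()
    sizes = labels.value_counts().reindex(list(SUBTYPES), fill_value=0)
    rows = []
    for gene in freqs["gene"]:
        altered = set(hits.loc[hits["gene"] == gene, "sample"])
        alt = np.array([sum(labels[s] == c for s in altered) for c in SUBTYPES])
        cont = np.vstack([alt, sizes.to_numpy() - alt])
        res = fisher_exact_rxc(cont, seed=seed)
        rows.append({"gene": gene,
                     **{f"altered_{c}": int(a) for c, a in zip(SUBTYPES, alt)},
                     "p": res.p, "method": res.method})
    return pd.DataFrame(rows)
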