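"""Consensus of TF-rule and ML subtype calls, with the label-agreement chi-square test.

A sample gets a consensus label only when the TF-based call and the ML call
agree.  For samples the strict TF rule assigned, the strict label is
compared with the ML label; for strict-unassigned ("borderline") samples
the relaxed TF label is used instead, rescuing part of the twilight zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DegenerateTableError
from .labeling import SUBTYPES, UNASSIGNED


@dataclass
class ConsensusResult:
    table: pd.DataFrame            # per-sample tf_call, ml_call, consensus_label, ...
    agreement_table: pd.DataFrame  # 4x4 tf label x ml label
    n_consensus: int

    @property
    def consensus_labels(self) -> pd.Series:
        return self.table["consensus_label"]


def _as_series(calls, name: str) -> pd.Series:
    if isinstance(calls, pd.Series):
        return calls.rename(name)
    return pd.Series({c.sample_id: c.label for c in calls}, name=name)


def consensus_labels(tf_strict, tf_relaxed, ml) -> ConsensusResult:
    """Combine strict/relaxed TF calls with ML calls into consensus labels.

    All three call sets must cover the same sample universe.  The effective
    TF call is the strict label where assigned, else the relaxed label; the
    consensus label equals it iff it matches the ML call, otherwise ``none``.
    """
    s = _as_series(tf_strict, "tf_strict")
    r = _as_series(tf_relaxed, "tf_relaxed")
    m = _as_series(ml, "ml_call")
    if not (set(s.index) == set(r.index) == set(m.index)):
        raise ContractError("tf_strict, tf_relaxed and ml must cover the same samples")
    r = r.loc[s.index]
    m = m.loc[s.index]
    borderline = s == UNASSIGNED
    tf_eff = s.where(~borderline, r).rename("tf_call")
    cons = tf_eff.where(tf_eff == m, "none").rename("consensus_label")
    table = pd.concat([s, r, m, tf_eff, cons, borderline.rename("borderline")],
                      axis=1)
    agree = pd.DataFrame(0, index=list(SUBTYPES), columns=list(SUBTYPES))
    for tfl, mll in zip(tf_eff, m):
        agree.loc[tfl, mll] += 1
    return ConsensusResult(table, agree, int((cons != "none").sum()))


def chi2_agreement(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction (the agreement table has df > 1).  Returns
    (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ContractError("table must be a 2-D non-negative count matrix")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column margin")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
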