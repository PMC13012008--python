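"""Synthetic SCLC cohort generator with planted NAPY structure.

Generates cohorts carrying exactly the statistical structure the pipeline
assumes: four subtypes each defined by one elevated lineage TF, a
co-regulated downstream gene program per TF, independent background noise
genes, a tunable fraction of borderline samples (two TFs co-elevated
within the strict rule's margin), subtype-enriched genomic alterations,
and subtype-dependent exponential survival with clinical covariates.
Everything flows from one seed through per-component sub-streams, so the
outputs are bit-reproducible and adding genes does not perturb the
survival draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .expression import ExpressionMatrix
from .labeling import TF_TO_LABEL
from .programs import TFProgram

#: subtype proportions mirroring a strictly TF-labeled SCLC cohort
DEFAULT_PROPORTIONS = {"A": 0.33, "N": 0.32, "P": 0.13, "Y": 0.22}
LABEL_TO_TF = {v: k for k, v in TF_TO_LABEL.items()}


def default_alteration_spec() -> dict:
    """Per-gene, per-subtype alteration probabilities.

    Defaults emulate the alteration landscape of SCLC cohorts: near
    universal TP53/RB1 inactivation, frequent LRP1B/KMT2D events spread
    across subtypes, MYCL amplification enriched in SCLC-A, and a milder
    RET enrichment in SCLC-Y.
    """
    flat = lambda p: {"A": p, "N": p, "P": p, "Y": p}
    return {
        ("TP53", "snv"): flat(0.95),
        ("RB1", "snv"): flat(0.74),
        ("LRP1B", "snv"): flat(0.27),
        ("KMT2D", "snv"): flat(0.17),
        ("PTEN", "deletion"): flat(0.14),
        ("MYCL", "amplification"): {"A": 0.115, "N": 0.051, "P": 0.028, "Y": 0.013},
        ("RET", "snv"): {"A": 0.047, "N": 0.042, "P": 0.056, "Y": 0.133},
    }


def default_survival_spec() -> dict:
    """Exponential OS per subtype plus covariate effects.

    Baseline median OS (months) per subtype reflects the worse prognosis of
    SCLC-P; male sex and a low T-effector score carry positive log hazards.
    Censoring is exponential (mean 40 months) with administrative cutoff at
    60 months.
    """
    return {
        "median_months": {"A": 13.8, "N": 10.1, "P": 7.3, "Y": 9.9},
        "log_hr_male": 0.35,
        "log_hr_teff": -0.30,      # per z-unit of T-effector score
        "censor_mean_months": 40.0,
        "admin_censor_months": 60.0,
    }


@dataclass
class SimulationConfig:
    n_samples: int = 400
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_noise_genes: int = 400
    program_size: int = 20
    tf_shift: float = 2.0          # z-units the subtype's TF is elevated
    tf_noise_sd: float = 0.4       # sd of TF-gene expression around its mean
    program_corr: float = 0.7      # target Pearson r of program genes to TF
    borderline_fraction: float = 0.28
    heavy_tails: bool = False      # t(5) noise instead of Gaussian
    alteration_spec: dict = field(default_factory=default_alteration_spec)
    survival_spec: dict = field(default_factory=default_survival_spec)
    base_expression: float = 5.0   # log2(TPM+1) offset of generated genes
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DomainError("subtype proportions must sum to 1")
        if not (0 <= self.borderline_fraction < 1):
            raise DomainError("borderline_fraction must be in [0, 1)")
        if not (abs(self.program_corr) < 1):
            raise DomainError("|program_corr| must be < 1")


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix   # log2(TPM+1) scale
    labels: pd.Series              # planted subtype per sample
    borderline: pd.Series          # bool per sample
    programs: dict[str, TFProgram]  # planted downstream programs per TF
    alterations: pd.DataFrame      # long format (gene, sample, alteration_class)
    survival: pd.DataFrame         # time, event, covariates per sample


def _noise(rng: np.random.Generator, size, heavy: bool) -> np.ndarray:
    if heavy:
        df = 5.0
        return rng.standard_t(df, size=size) / np.sqrt(df / (df - 2.0))
    return rng.standard_normal(size=size)


def simulate(cfg: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw one synthetic cohort under the configured conditions."""
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_expr, rng_alt, rng_surv = (np.random.default_rng(s)
                                   for s in ss.spawn(3))
    n = cfg.n_samples
    subtypes = list(cfg.subtype_proportions)
    probs = np.array([cfg.subtype_proportions[s] for s in subtypes])
    labels = pd.Series(
        rng_expr.choice(subtypes, size=n, p=probs),
        index=[f"S{i + 1:04d}" for i in range(n)], name="label")
    samples = labels.index

    n_border = int(round(cfg.borderline_fraction * n))
    border_idx = rng_expr.choice(n, size=n_border, replace=False)
    borderline = pd.Series(False, index=samples, name="borderline")
    borderline.iloc[border_idx] = True

    tf_genes = [LABEL_TO_TF[s] for s in subtypes]
    # latent TF activities: tf_noise_sd spread for every sample, plus the
    # tf_shift elevation in the TF's own subtype
    latent = np.zeros((4, n))
    for t in range(4):
        own = (labels == subtypes[t]).to_numpy()
        latent[t] = (cfg.tf_shift * own
                     + cfg.tf_noise_sd * _noise(rng_expr, n, cfg.heavy_tails))
    # borderline samples: a second TF trails the subtype's own TF by less
    # than the strict margin *in cohort z units*, so the strict rule rejects
    # them while the relaxed argmax still recovers the planted label
    mu = latent.mean(axis=1)
    sd = latent.std(axis=1, ddof=1)
    for i in border_idx:
        own_t = subtypes.index(labels.iloc[i])
        others = [t for t in range(4) if t != own_t]
        second = int(rng_expr.choice(others))
        z_own = (latent[own_t, i] - mu[own_t]) / sd[own_t]
        gap = rng_expr.uniform(0.0, 0.2)
        latent[second, i] = mu[second] + (z_own - gap) * sd[second]

    gene_rows = {}
    for t, tf in enumerate(tf_genes):
        gene_rows[tf] = cfg.base_expression + latent[t]
    programs: dict[str, TFProgram] = {}
    rho = cfg.program_corr
    for t, tf in enumerate(tf_genes):
        z_tf = (latent[t] - latent[t].mean()) / latent[t].std(ddof=1)
        genes = [f"{tf}_TGT{j + 1:02d}" for j in range(cfg.program_size)]
        for g in genes:
            x = rho * z_tf + np.sqrt(1 - rho**2) * _noise(rng_expr, n,
                                                          cfg.heavy_tails)
            gene_rows[g] = cfg.base_expression + x
        programs[tf] = TFProgram(tf, genes)
    for j in range(cfg.n_noise_genes):
        base = rng_expr.uniform(1.0, 8.0)
        gene_rows[f"BG{j + 1:04d}"] = base + _noise(rng_expr, n, cfg.heavy_tails)

    values = pd.DataFrame(gene_rows).T
    values.columns = samples
    values = values.clip(lower=0.0)  # keep the log2(TPM+1) scale non-negative
    expression = ExpressionMatrix(values, "log2_tpm1")

    alt_rows = []
    for (gene, alt_class), per_subtype in sorted(cfg.alteration_spec.items()):
        p_vec = labels.map(per_subtype).to_numpy(dtype=float)
        hits = rng_alt.random(n) < p_vec
        for s in samples[hits]:
            alt_rows.append({"gene": gene, "sample": s,
                             "alteration_class": alt_class})
    alterations = pd.DataFrame(alt_rows,
                               columns=["gene", "sample", "alteration_class"])

    spec = cfg.survival_spec
    hazards = {s: np.log(2.0) / spec["median_months"][s] for s in subtypes}
    sex = np.where(rng_surv.random(n) < 0.5, "male", "female")
    teff = rng_surv.standard_normal(n)
    tam = rng_surv.standard_normal(n)
    lot = np.where(rng_surv.random(n) < 0.37, ">1", "1")
    stage = np.where(rng_surv.random(n) < 0.87, "IV", "I-III")
    therapy = rng_surv.choice(["chemo+ici", "chemo", "mixed"], size=n,
                              p=[0.45, 0.25, 0.30])
    log_hr = (np.log([hazards[s] for s in labels])
              + spec["log_hr_male"] * (sex == "male")
              + spec["log_hr_teff"] * teff)
    times = rng_surv.exponential(scale=1.0 / np.exp(log_hr))
    censor = np.minimum(rng_surv.exponential(spec["censor_mean_months"], size=n),
                        spec["admin_censor_months"])
    event = times <= censor
    obs = np.minimum(times, censor)
    survival = pd.DataFrame({
        "time": np.maximum(obs, 1e-3), "event": event, "subtype": labels,
        "sex": sex, "teff_score": teff, "tam_score": tam,
        "lines_of_therapy": lot, "stage": stage, "therapy": therapy,
    }, index=samples)

    return SimulatedCohort(expression, labels, borderline, programs,
                           alterations, survival)


def make_worked_example() -> SimulatedCohort:
    """Tiny deterministic cohort (12 samples, 25 genes) for docs and golden tests.

    Three samples per subtype; sample S012 is borderline (NEUROD1 and ASCL1
    within 0.3 z after cohort scaling).  Each TF has two planted downstream
    genes (k = 2); gene YSIG1/YSIG2 form a Y-high two-gene signature; the
    remaining genes are flat background.
    """
    samples = [f"S{i + 1:03d}" for i in range(12)]
    # subtype plan: A A A N N N P P P Y Y  + borderline (A-vs-N) last
    labels = pd.Series(["A", "A", "A", "N", "N", "N", "P", "P", "P", "Y", "Y", "N"],
                       index=samples, name="label")
    borderline = pd.Series([False] * 11 + [True], index=samples, name="borderline")

    hi, lo = 8.0, 3.0
    blocks = {
        "A": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "N": [0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        "P": [0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0],
        "Y": [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0],
    }
    jitter = [0.0, 0.2, -0.2, 0.1, -0.1, 0.3, 0.2, 0.0, -0.2, 0.1, -0.1, 0.0]

    def row(block, scale=1.0, offset=0.0):
        return [lo + (hi - lo) * b * scale + offset + j
                for b, j in zip(blocks[block], jitter)]

    rows = {}
    for tf, letter in (("NEUROD1", "N"), ("ASCL1", "A"),
                       ("POU2F3", "P"), ("YAP1", "Y")):
        r = row(letter)
        rows[tf] = r
    # borderline sample S012: NEUROD1 just above ASCL1, within the margin
    rows["NEUROD1"][11] = 7.0
    rows["ASCL1"][11] = 6.8
    for tf, letter in (("NEUROD1", "N"), ("ASCL1", "A"),
                       ("POU2F3", "P"), ("YAP1", "Y")):
        # two downstream genes per TF: strongly correlated copies of the TF row
        rows[f"{tf}_TGT01"] = [v * 0.9 + 0.5 for v in rows[tf]]
        rows[f"{tf}_TGT02"] = [v * 0.8 + 1.0 for v in rows[tf]]
    rows["YSIG1"] = [v + 0.3 for v in rows["YAP1"]]
    rows["YSIG2"] = [v * 1.1 - 0.2 for v in rows["YAP1"]]
    for j in range(7):
        rows[f"BG{j + 1:02d}"] = [4.0 + 0.1 * ((i * (j + 3)) % 5) for i in range(12)]

    values = pd.DataFrame(rows, index=samples).T
    expression = ExpressionMatrix(values, "log2_tpm1")
    programs = {tf: TFProgram(tf, [f"{tf}_TGT01", f"{tf}_TGT02"])
                for tf in ("NEUROD1", "ASCL1", "POU2F3", "YAP1")}
    alterations = pd.DataFrame(columns=["gene", "sample", "alteration_class"])
    survival = pd.DataFrame({
        "time": [12.0, 10.0, 15.0, 9.0, 11.0, 8.0, 5.0, 6.0, 4.0, 9.5, 7.5, 10.5],
        "event": [True, True, False, True, True, True, True, True, True,
                  False, True, True],
        "subtype": labels, "sex": ["male", "female"] * 6,
        "teff_score": [0.5, -0.5, 0.0, 1.0, -1.0, 0.2, -0.2, 0.8, -0.8,
                       0.3, -0.3, 0.0],
        "stage": ["IV"] * 12,
    }, index=samples)
    return SimulatedCohort(expression, labels, borderline, programs,
                           alterations, survival)
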