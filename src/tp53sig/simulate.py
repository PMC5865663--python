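"""Synthetic cohorts with the statistical structure the analysis assumes.

The real FFPE/FF cohorts behind the assay are not public, so every input
the pipeline consumes can be generated here instead: expression counts in
which signature-mutant tumours show elevated up-gene and suppressed
down-gene counts, paired FFPE replicates with multiplicative log-normal
noise, exponential proportional-hazards relapse times tied to signature
status, clinical covariates whose MT/WT imbalances follow the directions
seen in early-stage breast cancer (ER/PgR negativity, HER2 positivity and
high grade enriched among signature-mutant tumours), and TCGA-like
mutation / copy-number / immune-expression tables in which the mutant-type
group carries the heavier burdens.

Every generator is a pure function of its configuration and seed.  The
module also owns the frozen 30-sample canonical learning fixture used to
exercise cutoff calibration end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signature import ExpressionMatrix, GeneSignature, load_signature

__all__ = [
    "SyntheticConfig",
    "CohortBundle",
    "default_signature",
    "generate_cohort",
    "generate_paired_ffpe",
    "generate_tcga_like",
    "canonical_learning_fixture",
    "CANONICAL_WT_SCORES",
    "CANONICAL_MT_SCORES",
]


def default_signature() -> GeneSignature:
    """Placeholder 22+9+5 panel (UP01..UP22, DN01..DN09, CTL01..CTL05).

    The assay's real gene identities are supplied at run time through a
    signature configuration file; synthetic cohorts use positional names.
    """
    return load_signature(
        {
            "up": [f"UP{i:02d}" for i in range(1, 23)],
            "down": [f"DN{i:02d}" for i in range(1, 10)],
            "control": [f"CTL{i:02d}" for i in range(1, 6)],
        }
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generators.

    Defaults mirror the validation cohort the signature was calibrated
    against: 64 signature-mutant vs 110 wild-type stage I-II tumours, a
    mutant-vs-wild-type relapse hazard ratio of 4.9, and an up/down
    expression effect (x2 / x0.5) that separates the two score
    distributions about fourfold.
    """

    seed: int = 0
    n_mutant: int = 64
    n_wildtype: int = 110
    up_effect: float = 2.0  # multiplicative, applied to up-genes in mutants
    down_effect: float = 0.5  # multiplicative, applied to down-genes in mutants
    baseline_log_mean: float = 6.0  # natural-log count scale (~400 counts)
    baseline_log_sd: float = 1.0  # spread of per-gene baselines
    sample_log_sd: float = 0.3  # per-sample biological/technical noise (log scale)
    ffpe_noise_sd: float = 0.1  # FFPE replicate noise on the log scale
    hazard_ratio: float = 4.9  # MT vs WT relapse hazard
    baseline_hazard: float = 0.002  # WT events per month
    censor_horizon: float = 60.0  # months of follow-up
    tp53_mut_fraction_mt: float = 0.9  # P(structural TP53 mutation | signature MT)
    tp53_mut_fraction_wt: float = 0.1  # P(structural TP53 mutation | signature WT)
    mutation_rate_mt: float = 0.05  # per background gene, MT samples
    mutation_rate_wt: float = 0.02  # per background gene, WT samples
    cnv_effect: float = 2.0  # CNV-burden location shift, MT vs WT
    immune_effect: float = 2.0  # PD-L1/CD8B location shift, MT vs WT
    n_background_genes: int = 200

    def __post_init__(self) -> None:
        if not (self.up_effect > 1.0 > self.down_effect > 0.0):
            if not (self.up_effect == self.down_effect == 1.0):  # null configuration allowed
                raise ValueError("expected up_effect > 1 > down_effect > 0 (or both exactly 1 for a null)")
        for name in ("tp53_mut_fraction_mt", "tp53_mut_fraction_wt", "mutation_rate_mt", "mutation_rate_wt"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_mutant < 1 or self.n_wildtype < 1:
            raise ValueError("both groups need at least one sample")
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0 or self.censor_horizon <= 0:
            raise ValueError("hazard parameters must be positive")
        if min(self.sample_log_sd, self.ffpe_noise_sd, self.baseline_log_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class CohortBundle:
    """Everything the pipeline consumes for one synthetic cohort."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # categorical covariates + age
    outcomes: pd.DataFrame  # sample_id-indexed time/event
    tp53_mutation: pd.Series  # structural-mutation truth label (0/1)
    true_status: pd.Series  # generating signature status (MT/WT)
    mutations: pd.DataFrame | None = None  # MAF-like (sample_id, gene_symbol)
    cnv_burden: pd.Series | None = None
    smn: pd.Series | None = None
    immune_expression: pd.DataFrame | None = None  # PD-L1 / CD8B columns


# MT-vs-WT covariate set-points (positive/affirmative rate per group),
# matching the qualitative imbalances of an early-stage cohort.
_CLINICAL_RATES = {
    "er_positive": (0.44, 0.87),
    "pgr_positive": (0.25, 0.72),
    "her2_positive": (0.19, 0.04),
    "node_positive": (0.39, 0.27),
    "chemo": (0.66, 0.35),
    "endocrine": (0.39, 0.89),
}
_STAGE_PROBS = {"MT": (0.375, 0.4375, 0.1875), "WT": (0.555, 0.282, 0.163)}
_GRADE_PROBS = {"MT": (0.047, 0.297, 0.656), "WT": (0.381, 0.524, 0.095)}


def _draw_counts(
    rng: np.random.Generator,
    mutant: np.ndarray,
    signature: GeneSignature,
    cfg: SyntheticConfig,
) -> pd.DataFrame:
    genes = list(signature.all_genes)
    n = mutant.size
    base = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes))
    noise = rng.normal(0.0, cfg.sample_log_sd, size=(n, len(genes)))
    log_counts = base[None, :] + noise
    effect = np.ones((n, len(genes)))
    up_idx = [genes.index(g) for g in signature.up_genes]
    down_idx = [genes.index(g) for g in signature.down_genes]
    effect[np.ix_(mutant.astype(bool), up_idx)] = cfg.up_effect
    effect[np.ix_(mutant.astype(bool), down_idx)] = cfg.down_effect
    counts = np.rint(np.exp(log_counts) * effect).astype(float)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(counts, index=samples, columns=genes)


def generate_cohort(config: SyntheticConfig, signature: GeneSignature | None = None) -> CohortBundle:
    """One full cohort: expression, clinical covariates, survival, TP53 labels.

    Per-gene count baselines are log-normal; mutant samples have up-genes
    multiplied by ``up_effect`` and down-genes by ``down_effect``.  Relapse
    times are exponential with hazard ``baseline_hazard x
    hazard_ratio^mutant`` and administrative censoring at
    ``censor_horizon`` months.  Structural TP53 labels agree with the
    generating status with the configured per-group fractions, so
    calibration on this cohort faces the realistic degree of label noise.
    """
    if signature is None:
        signature = default_signature()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    mutant = np.concatenate([np.ones(cfg.n_mutant, dtype=int), np.zeros(cfg.n_wildtype, dtype=int)])
    counts = _draw_counts(rng, mutant, signature, cfg)
    samples = counts.index
    true_status = pd.Series(np.where(mutant == 1, "MT", "WT"), index=samples, name="true_status")

    # structural-mutation truth label, noisy around the generating status
    p_mut = np.where(mutant == 1, cfg.tp53_mut_fraction_mt, cfg.tp53_mut_fraction_wt)
    tp53 = pd.Series((rng.random(mutant.size) < p_mut).astype(int), index=samples, name="tp53_mutation")

    # relapse-free survival: exponential proportional hazards, censored at horizon
    hazard = cfg.baseline_hazard * cfg.hazard_ratio ** mutant
    latent = rng.exponential(1.0 / hazard)
    time = np.minimum(latent, cfg.censor_horizon)
    event = (latent <= cfg.censor_horizon).astype(int)
    outcomes = pd.DataFrame({"time": time, "event": event}, index=samples)
    outcomes.index.name = "sample_id"

    clin = {"age": np.clip(np.rint(rng.normal(58.0, 12.0, mutant.size)), 26, 98).astype(int)}
    for name, (p_mt, p_wt) in _CLINICAL_RATES.items():
        p = np.where(mutant == 1, p_mt, p_wt)
        clin[name] = (rng.random(mutant.size) < p).astype(int)
    stage_levels, grade_levels = np.array(["I", "IIA", "IIB"]), np.array([1, 2, 3])
    stage, grade = [], []
    for m in mutant:
        key = "MT" if m else "WT"
        stage.append(rng.choice(stage_levels, p=np.asarray(_STAGE_PROBS[key]) / sum(_STAGE_PROBS[key])))
        grade.append(rng.choice(grade_levels, p=np.asarray(_GRADE_PROBS[key]) / sum(_GRADE_PROBS[key])))
    clin["stage"] = stage
    clin["grade"] = grade
    clinical = pd.DataFrame(clin, index=samples)
    clinical.index.name = "sample_id"

    return CohortBundle(
        expression=ExpressionMatrix(counts, platform="ncounter"),
        clinical=clinical,
        outcomes=outcomes,
        tp53_mutation=tp53,
        true_status=true_status,
    )


def generate_paired_ffpe(ff: ExpressionMatrix, noise_sd: float, seed: int) -> ExpressionMatrix:
    """FFPE replicate of an FF matrix: multiplicative log-normal noise, rounded.

    ``ffpe = round(count * exp(eps))`` with ``eps ~ Normal(0, noise_sd)``;
    zero counts stay zero.  Same samples, genes and ordering as the input.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x = ff.counts.to_numpy(dtype=float)
    eps = rng.normal(0.0, noise_sd, size=x.shape)
    noisy = np.where(x > 0, np.rint(x * np.exp(eps)), 0.0)
    return ExpressionMatrix(pd.DataFrame(noisy, index=ff.counts.index, columns=ff.counts.columns), platform=ff.platform)


def generate_tcga_like(config: SyntheticConfig, signature: GeneSignature | None = None) -> CohortBundle:
    """TCGA-flavoured bundle: cohort plus mutation, CNV, SMN and immune tables.

    Background genes (BG0001..) mutate per sample with the per-status
    Bernoulli rates; TP53 records follow the structural-mutation label so
    the signature-MT-without-TP53-mutation subgroup is non-empty.  CNV
    burden and PD-L1/CD8B expression are log-normal with the configured
    MT-vs-WT location shifts; SMN is the per-sample distinct mutated gene
    count of the generated table.
    """
    bundle = generate_cohort(config, signature)
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    samples = bundle.expression.counts.index
    mutant = (bundle.true_status == "MT").to_numpy()

    bg_genes = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    rate = np.where(mutant, cfg.mutation_rate_mt, cfg.mutation_rate_wt)
    hits = rng.random((len(samples), len(bg_genes))) < rate[:, None]
    rec_s, rec_g = np.nonzero(hits)
    records = [(samples[i], bg_genes[j]) for i, j in zip(rec_s, rec_g)]
    records += [(s, "TP53") for s, m in bundle.tp53_mutation.items() if m == 1]
    mutations = pd.DataFrame(records, columns=["sample_id", "gene_symbol"]).sort_values(
        ["sample_id", "gene_symbol"], ignore_index=True
    )

    smn = mutations.groupby("sample_id")["gene_symbol"].nunique().reindex(samples, fill_value=0)
    smn.name = "smn"

    cnv = pd.Series(
        np.exp(rng.normal(np.log(50.0) + np.log(cfg.cnv_effect) * mutant, 0.5)),
        index=samples,
        name="cnv_burden",
    )
    immune = pd.DataFrame(
        {
            "PDL1": np.exp(rng.normal(np.log(100.0) + np.log(cfg.immune_effect) * mutant, 0.5)),
            "CD8B": np.exp(rng.normal(np.log(80.0) + np.log(cfg.immune_effect) * mutant, 0.5)),
        },
        index=samples,
    )
    immune.index.name = "sample_id"

    return replace_fields(bundle, mutations=mutations, cnv_burden=cnv, smn=smn, immune_expression=immune)


def replace_fields(bundle: CohortBundle, **kwargs) -> CohortBundle:
    data = {**bundle.__dict__, **kwargs}
    return CohortBundle(**data)


# ---------------------------------------------------------------------------
# Canonical learning fixture: 30 (risk score, TP53 structural label) pairs
# emulating a calibration cohort in which 14 of 30 patients carry a TP53
# mutation.  The values are artifact-defined (the study's scores are not
# public) and frozen: the accuracy-maximising cutoff lies in the open
# interval (0.75, 0.79) with 27/30 samples correct.

CANONICAL_WT_SCORES: tuple[float, ...] = (
    0.30, 0.35, 0.40, 0.42, 0.45, 0.48, 0.50, 0.52,
    0.58, 0.60, 0.62, 0.65, 0.70, 0.75, 1.06, 1.08,
)
CANONICAL_MT_SCORES: tuple[float, ...] = (
    0.55, 0.79, 0.80, 0.85, 0.90, 0.95, 1.00, 1.05,
    1.10, 1.15, 1.20, 1.30, 1.40, 1.50,
)


def canonical_learning_fixture() -> pd.DataFrame:
    """The frozen 30-sample calibration fixture.

    Returns a DataFrame with columns ``risk_score`` and ``tp53_mutation``
    (0 = wild type, 1 = mutant): 16 wild-type followed by 14 mutant
    samples, in the canonical order.
    """
    scores = list(CANONICAL_WT_SCORES) + list(CANONICAL_MT_SCORES)
    labels = [0] * len(CANONICAL_WT_SCORES) + [1] * len(CANONICAL_MT_SCORES)
    out = pd.DataFrame(
        {"risk_score": scores, "tp53_mutation": labels},
        index=[f"L{i:02d}" for i in range(1, 31)],
    )
    out.index.name = "sample_id"
    return out
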