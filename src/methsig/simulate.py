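"""Synthetic cohort generation with full ground truth.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes: paired tumor/normal beta values with planted
hyper-/hypomethylation effects, low-rank nonnegative signature structure with
cancer-type enrichment, mutation -> expression -> signature causal chains with
a shared confounder, and survival / immunotherapy outcome models driven by a
designated signature's activity.

Beta-value noise uses the two-parameter beta distribution parameterized by
(mean, concentration): ``Beta(mu * c, (1 - mu) * c)``, which has mean ``mu``
and variance ``mu (1 - mu) / (c + 1)`` — the natural heteroscedastic noise
family on [0, 1].  ``concentration = inf`` is the noiseless limit and emits
the mean matrix exactly.

One integer seed drives a named sub-stream per operation (via
``numpy.random.SeedSequence`` spawn keys), so each stage is individually
reproducible and stages do not perturb each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .containers import BetaMatrix, GroundTruth

# stable sub-stream ids; appending new stages must not renumber old ones
_STREAMS = {
    "paired": 1,
    "signature": 2,
    "genotype": 3,
    "clinical": 4,
    "annotation": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults match the scale the pipeline is exercised at: 40 tumor/normal
    pairs across 3 cancer types, 2,000 probes with 5% planted hyper- and 5%
    hypomethylated positions of effect size |delta beta| = 0.3, beta-noise
    concentration 100 (sd ~0.03-0.05 at mid-range means), 4 planted
    signatures, and a causal expression -> activity effect of 2.
    """

    n_pairs: int = 40
    n_tumor_only: int = 0
    n_probes: int = 2000
    n_cancer_types: int = 3
    frac_hyper: float = 0.05
    frac_hypo: float = 0.05
    delta_hyper: float = 0.3
    delta_hypo: float = -0.3
    concentration: float = 100.0
    cancer_effect_sd: float = 0.02
    k_true: int = 4
    signature_noise_sd: float = 0.02
    n_genes: int = 50
    n_determinant_genes: int = 5
    mut_rate: float = 0.15
    instrument_strength: float = 1.0
    causal_beta: float = 2.0
    confounder_sd: float = 1.0
    expression_noise_sd: float = 0.5
    activity_noise_sd: float = 0.5
    hazard_log_hr: float = float(np.log(2.0))
    baseline_hazard: float = 1.0 / 365.0
    censor_rate: float = 0.2
    ici_intercept: float = 0.0
    ici_activity_coef: float = -0.8
    ici_tp53_coef: float = 0.5
    ici_foxa1_coef: float = 0.3
    immune_spearman: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_hyper", "frac_hypo", "mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_hyper + self.frac_hypo > 1.0:
            raise ValueError("frac_hyper + frac_hypo must be <= 1")
        if self.frac_hyper > 0 and not self.delta_hyper > 0:
            raise ValueError("delta_hyper must be positive")
        if self.frac_hypo > 0 and not self.delta_hypo < 0:
            raise ValueError("delta_hypo must be negative")
        if abs(self.delta_hyper) >= 0.98 or abs(self.delta_hypo) >= 0.98:
            raise ValueError(
                "planted |delta beta| must stay below 0.98 so shifted means "
                "remain inside (0.01, 0.99) after clipping"
            )
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 tumor/normal pairs")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


def _beta_noise(
    rng: np.random.Generator, mean: np.ndarray, concentration: float
) -> np.ndarray:
    """Draw from Beta(mean * c, (1-mean) * c); deterministic mean at c=inf."""
    if np.isinf(concentration):
        return mean.copy()
    a = np.clip(mean, 1e-6, 1 - 1e-6) * concentration
    b = (1.0 - np.clip(mean, 1e-6, 1 - 1e-6)) * concentration
    return rng.beta(a, b)


def _cancer_labels(n: int, n_types: int) -> np.ndarray:
    return np.array([f"CT{1 + i % n_types}" for i in range(n)])


def simulate_paired_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, GroundTruth]:
    """Simulate a paired tumor/normal cohort with planted DMPs.

    Non-DMP probes share a baseline mean ``mu_j ~ U(0.05, 0.95)`` in both
    tissues; planted hyper (hypo) probes shift the tumor mean by
    ``delta_hyper`` (``delta_hypo``), clipped to (0.01, 0.99).  A small
    additive cancer-type baseline offset (sd ``cancer_effect_sd``, shared by
    both members of a pair) exercises the cancer-type covariate without
    inducing a tissue effect.
    """
    rng = _rng(config.seed, "paired")
    n_probes, n_pairs = config.n_probes, config.n_pairs

    n_hyper = int(round(config.frac_hyper * n_probes))
    n_hypo = int(round(config.frac_hypo * n_probes))
    dmp = rng.choice(n_probes, size=n_hyper + n_hypo, replace=False)
    hyper_idx = np.sort(dmp[:n_hyper])
    hypo_idx = np.sort(dmp[n_hyper:])

    mu = rng.uniform(0.05, 0.95, size=n_probes)
    tumor_mu = mu.copy()
    tumor_mu[hyper_idx] += config.delta_hyper
    tumor_mu[hypo_idx] += config.delta_hypo
    tumor_mu = np.clip(tumor_mu, 0.01, 0.99)

    cancer = _cancer_labels(n_pairs, config.n_cancer_types)
    types = sorted(set(cancer))
    type_offset = rng.normal(
        0.0, config.cancer_effect_sd, size=(n_probes, len(types))
    )
    t_idx = np.array([types.index(c) for c in cancer])

    # means per (probe, pair): baseline + cancer-type offset, tumor shifted
    normal_mean = np.clip(mu[:, None] + type_offset[:, t_idx], 0.01, 0.99)
    tumor_mean = np.clip(
        tumor_mu[:, None] + type_offset[:, t_idx], 0.01, 0.99
    )

    tumor_vals = _beta_noise(rng, tumor_mean, config.concentration)
    normal_vals = _beta_noise(rng, normal_mean, config.concentration)

    probe_ids = [f"cg{j:08d}" for j in range(n_probes)]
    cols, data, rows = [], [], []
    for i in range(n_pairs):
        pid = f"P{i:04d}"
        cols += [f"{pid}-T", f"{pid}-N"]
        rows.append((f"{pid}-T", pid, "tumor", cancer[i]))
        rows.append((f"{pid}-N", pid, "normal", cancer[i]))
        data += [tumor_vals[:, i], normal_vals[:, i]]
    values = pd.DataFrame(
        np.column_stack(data), index=probe_ids, columns=cols
    )
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue_type", "cancer_type"]
    ).set_index("sample_id")
    sheet["purity"] = np.nan
    is_tumor = sheet["tissue_type"] == "tumor"
    sheet.loc[is_tumor, "purity"] = rng.uniform(
        0.601, 1.0, size=int(is_tumor.sum())
    )

    truth = GroundTruth(hyper_idx=hyper_idx, hypo_idx=hypo_idx)
    return BetaMatrix(values, sheet), truth


def simulate_signature_cohort(
    config: SimulationConfig, n_samples: int | None = None
) -> tuple[BetaMatrix, GroundTruth]:
    """Simulate a tumor-only cohort with planted low-rank signature structure.

    ``true_E`` is sparse, nonnegative and column-normalized (each signature
    loads on its own probe block plus a small shared overlap); ``true_H`` is
    nonnegative with cancer-type-dependent activity levels so each signature
    is enriched in one cancer type.  Emits
    ``V = clip(true_E @ true_H + noise, 0, 1)``.
    """
    rng = _rng(config.seed, "signature")
    k = config.k_true
    n_probes = config.n_probes
    if n_samples is None:
        n_samples = config.n_pairs + config.n_tumor_only
    if k > min(n_probes, n_samples):
        raise ValueError(
            f"k_true={k} exceeds matrix dimensions "
            f"({n_probes} probes x {n_samples} samples)"
        )

    # dense loading matrix with signature-specific enriched probe blocks:
    # every probe carries a baseline weight in every signature and a 2-3x
    # boost in its own block, as in real DMP panels where probes are
    # informative for one signature but never silent elsewhere.  Keeping
    # max(E) close to the column mean is also what lets the complement
    # matrix 1 - V share the activity matrix (see compare_beta_orientation).
    block = n_probes // k
    E = rng.gamma(8.0, 1.0, size=(n_probes, k))
    for s in range(k):
        sl = slice(s * block, (s + 1) * block if s < k - 1 else n_probes)
        E[sl, s] *= rng.uniform(2.0, 3.0, size=sl.stop - sl.start)
    E /= E.sum(axis=0, keepdims=True)

    # each sample has a dominant signature (round robin) and its cancer type
    # follows from it, so every signature is enriched in one cancer type and
    # each cancer type hosts ceil(k / n_types) signatures
    dominant = np.arange(n_samples) % k
    cancer = np.array(
        [f"CT{1 + d % config.n_cancer_types}" for d in dominant]
    )
    H = rng.gamma(1.5, 1.0, size=(k, n_samples))
    H[dominant, np.arange(n_samples)] += rng.gamma(6.0, 1.0, size=n_samples)
    # near-constant activity totals per sample (a conserved methylation
    # budget): what makes beta- and (1-beta)-derived signatures agree
    H /= H.sum(axis=0, keepdims=True)
    H *= 1.0 + rng.normal(0.0, 0.02, size=n_samples)
    H = np.maximum(H, 0.0)
    # scale activities so the emitted matrix occupies the beta range
    peak = (E @ H).max()
    if peak > 0:
        H *= 0.9 / peak
    V = E @ H
    if config.signature_noise_sd > 0:
        V = V + rng.normal(0.0, config.signature_noise_sd, size=V.shape)
    V = np.clip(V, 0.0, 1.0)

    probe_ids = [f"cg{j:08d}" for j in range(n_probes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    values = pd.DataFrame(V, index=probe_ids, columns=sample_ids)
    sheet = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "tissue_type": "tumor",
            "cancer_type": cancer,
            "purity": rng.uniform(0.601, 1.0, size=n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(true_E=E, true_H=H)
    return BetaMatrix(values, sheet), truth


def simulate_genotype_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    target_signature: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate mutation and expression matrices with a planted causal chain.

    For each determinant gene ``j``: mutation status is Bernoulli(mut_rate);
    a shared confounder ``u_i ~ N(0, confounder_sd)`` enters both the
    expression equation and the signature activity, making expression an
    endogenous mediator while mutation status remains a valid instrument::

        mRNA_ij = a0 + a1 * SMS_ij + u_i + noise
        MS_i    = b0 + causal_beta * mRNA_ij + u_i + noise

    The designated signature's activity row in ``truth.true_H`` is
    overwritten with the structural outcome (summed over determinant genes'
    expression contributions).  Non-determinant genes get expression
    independent of the activity.  Genes whose realized mutation count is < 2
    after one resampling attempt are flagged unusable.

    Returns the binary gene x sample mutation matrix, the gene x sample
    expression matrix, and an updated ground truth.
    """
    if truth.true_H is None:
        raise ValueError("truth must carry true_H (run the signature cohort)")
    rng = _rng(config.seed, "genotype")
    n_genes = config.n_genes
    n_samples = truth.true_H.shape[1]
    n_det = min(config.n_determinant_genes, n_genes)

    mut = (rng.random((n_genes, n_samples)) < config.mut_rate).astype(int)
    unusable = []
    for g in range(n_genes):
        if mut[g].sum() < 2:
            warnings.warn(
                f"gene {g} drew <2 mutant samples; resampling once",
                stacklevel=2,
            )
            mut[g] = (rng.random(n_samples) < config.mut_rate).astype(int)
            if mut[g].sum() < 2:
                unusable.append(g)

    u = rng.normal(0.0, config.confounder_sd, size=n_samples)
    expr = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    det = np.arange(n_det)
    activity = np.zeros(n_samples)
    for g in det:
        expr[g] = (
            1.0
            + config.instrument_strength * mut[g]
            + u
            + rng.normal(0.0, config.expression_noise_sd, size=n_samples)
        )
        activity += config.causal_beta * expr[g]
    activity = (
        activity
        + u
        + rng.normal(0.0, config.activity_noise_sd, size=n_samples)
    )
    H = truth.true_H.copy()
    # keep activities nonnegative: shift to a positive floor
    H[target_signature] = activity - activity.min() + 1e-3

    genes = [f"G{g:04d}" for g in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    mut_df = pd.DataFrame(mut, index=genes, columns=samples)
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    new_truth = GroundTruth(
        hyper_idx=truth.hyper_idx,
        hypo_idx=truth.hypo_idx,
        true_E=truth.true_E,
        true_H=H,
        determinant_genes=det,
        causal_beta=config.causal_beta,
        survival_params=truth.survival_params,
        unusable_genes=np.array(unusable, int),
    )
    return mut_df, expr_df, new_truth


def simulate_clinical(
    config: SimulationConfig,
    truth: GroundTruth,
    target_signature: int = 0,
    cancer_types: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate clinical outcomes driven by one signature's activity.

    Survival is exponential with rate ``lambda0 * exp(hazard_log_hr * z)``
    where ``z`` is the standardized activity of the designated signature;
    censoring is independent exponential tuned so the expected censored
    fraction equals ``censor_rate``.  Age, stage and immune features carry a
    configurable rank-level association with activity (Gaussian-copula
    construction at Spearman level ``immune_spearman``).  ICI response is
    Bernoulli(logistic(c0 + c1 z + c2 TP53 + c3 FOXA1)).
    """
    if truth.true_H is None:
        raise ValueError("truth must carry true_H")
    rng = _rng(config.seed, "clinical")
    act = truth.true_H[target_signature]
    n = act.size
    sd = act.std()
    z = (act - act.mean()) / sd if sd > 0 else np.zeros(n)

    lam = config.baseline_hazard * np.exp(config.hazard_log_hr * z)
    event_t = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        ratio = config.censor_rate / (1.0 - config.censor_rate)
        censor_t = rng.exponential(1.0 / (lam * ratio))
        os_time = np.minimum(event_t, censor_t)
        os_event = (event_t <= censor_t).astype(int)
    else:
        os_time, os_event = event_t, np.ones(n, int)

    rho = config.immune_spearman
    mix = np.sqrt(max(0.0, 1.0 - rho**2))

    def correlated(scale=1.0, shift=0.0):
        return shift + scale * (rho * z + mix * rng.normal(size=n))

    age = np.clip(55 + 12 * correlated(), 18, 95)
    stage_latent = correlated()
    stage = np.where(stage_latent > np.median(stage_latent), "adv", "pri")
    tp53 = (rng.random(n) < 0.4).astype(int)
    foxa1 = correlated() + rng.normal(scale=0.5, size=n)
    lin = (
        config.ici_intercept
        + config.ici_activity_coef * z
        + config.ici_tp53_coef * tp53
        + config.ici_foxa1_coef * foxa1
    )
    response = np.where(
        rng.random(n) < 1.0 / (1.0 + np.exp(-lin)),
        "responder",
        "nonresponder",
    )
    table = pd.DataFrame(
        {
            "os_time": np.maximum(os_time, 1e-3),
            "os_event": os_event,
            "age": age,
            "stage_group": stage,
            "tp53_status": tp53,
            "foxa1_expr": foxa1,
            "response": response,
            "lymphocyte_infiltration": correlated(),
            "treg_fraction": 1.0 / (1.0 + np.exp(-correlated())),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id"),
    )
    if cancer_types is not None:
        table["cancer_type"] = np.asarray(cancer_types)
    return table


def simulate_probe_annotation(
    probe_ids,
    seed: int = 0,
    hyper_idx: np.ndarray | None = None,
    hypo_idx: np.ndarray | None = None,
    frac_snp: float = 0.02,
    frac_sex: float = 0.03,
) -> pd.DataFrame:
    """Random probe annotation exercising every QC and context category.

    When planted DMP index sets are given, hyper probes are biased toward CpG
    islands and hypo probes toward open sea, mirroring the genomic context
    asymmetry expected of cancer methylomes; planted DMPs are never flagged
    as SNP or sex-chromosome probes (QC must not silently remove the planted
    signal).
    """
    rng = _rng(seed, "annotation")
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    hyper = set() if hyper_idx is None else set(np.asarray(hyper_idx))
    hypo = set() if hypo_idx is None else set(np.asarray(hypo_idx))
    planted = hyper | hypo

    chrom = np.array([f"chr{1 + i % 22}" for i in range(n)], object)
    free = np.array([i for i in range(n) if i not in planted])
    rng.shuffle(free)
    n_snp = int(frac_snp * n)
    n_sex = int(frac_sex * n)
    snp_flag = np.zeros(n, bool)
    snp_flag[free[:n_snp]] = True
    chrom[free[n_snp : n_snp + n_sex]] = rng.choice(
        ["chrX", "chrY"], size=n_sex
    )

    rel = rng.choice(
        ["island", "shore", "shelf", "open_sea"],
        size=n,
        p=[0.3, 0.25, 0.1, 0.35],
    )
    for i in hyper:
        rel[i] = rng.choice(["island", "shore"], p=[0.8, 0.2])
    for i in hypo:
        rel[i] = rng.choice(["open_sea", "shelf"], p=[0.8, 0.2])
    region = rng.choice(["TSS", "gene_body", "other"], size=n, p=[0.4, 0.4, 0.2])
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "pos": rng.integers(1, 2_000_000, size=n),
            "island_relation": rel,
            "region": region,
            "gene": [f"G{i % 500:04d}" for i in range(n)],
            "snp_flag": snp_flag,
        }
    )


@dataclass
class StudyData:
    """All inputs of one simulated end-to-end study."""

    paired: BetaMatrix
    paired_truth: GroundTruth
    tumors: BetaMatrix
    tumor_truth: GroundTruth
    mutations: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    annotation: pd.DataFrame


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate a coherent study: paired cohort, tumor cohort, omics, clinic.

    The paired cohort carries the planted DMPs; the tumor-only cohort
    (``n_tumor_only`` samples, at least 3 * k_true) carries low-rank
    signature structure planted on the DMP probes, with the first
    signature's activity rewired by the mutation -> expression causal chain
    before the methylation matrix is emitted, so projection downstream sees
    the causal structure.  Clinical outcomes are driven by that same
    activity.
    """
    paired, paired_truth = simulate_paired_cohort(config)
    n_tumors = max(config.n_tumor_only, 3 * config.k_true, 30)

    dmp_idx = np.concatenate([paired_truth.hyper_idx, paired_truth.hypo_idx])
    dmp_idx = np.sort(dmp_idx)
    if dmp_idx.size < config.k_true:
        raise ValueError("too few planted DMPs to carry signature structure")

    sig_cfg = SimulationConfig(
        **{
            **{f: getattr(config, f) for f in config.__dataclass_fields__},
            "n_probes": int(dmp_idx.size),
            "frac_hyper": 0.0,
            "frac_hypo": 0.0,
        }
    )
    sig_m, sig_truth = simulate_signature_cohort(sig_cfg, n_samples=n_tumors)
    mut, expr, sig_truth = simulate_genotype_expression(
        sig_cfg, sig_truth, target_signature=0
    )
    # rescale the rewired activity row back to the other rows' scale, then
    # re-emit the methylation matrix from the final activities
    H = sig_truth.true_H.copy()
    if H.shape[0] > 1 and H[0].max() > 0:
        H[0] *= H[1:].max() / H[0].max()
    peak = (sig_truth.true_E @ H).max()
    if peak > 0:
        H *= 0.9 / peak
    rng = _rng(config.seed, "signature")
    V = sig_truth.true_E @ H
    if config.signature_noise_sd > 0:
        V = V + rng.normal(0.0, config.signature_noise_sd, size=V.shape)
    V = np.clip(V, 0.0, 1.0)

    # embed the signature-bearing probes at the paired cohort's DMP ids;
    # remaining probes get independent baseline noise
    rng2 = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(9,))
    )
    full = _beta_noise(
        rng2,
        np.tile(
            rng2.uniform(0.05, 0.95, size=config.n_probes)[:, None],
            (1, n_tumors),
        ),
        config.concentration,
    )
    full[dmp_idx, :] = V
    probe_ids = paired.probe_ids
    sample_ids = [f"S{i:04d}" for i in range(n_tumors)]
    values = pd.DataFrame(full, index=probe_ids, columns=sample_ids)
    cancer = _cancer_labels(n_tumors, config.n_cancer_types)
    sheet = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "tissue_type": "tumor",
            "cancer_type": cancer,
            "purity": rng2.uniform(0.601, 1.0, size=n_tumors),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    tumors = BetaMatrix(values, sheet)
    tumor_truth = GroundTruth(
        hyper_idx=paired_truth.hyper_idx,
        hypo_idx=paired_truth.hypo_idx,
        true_E=sig_truth.true_E,
        true_H=H,
        determinant_genes=sig_truth.determinant_genes,
        causal_beta=sig_truth.causal_beta,
        survival_params=(config.hazard_log_hr, config.baseline_hazard),
        unusable_genes=sig_truth.unusable_genes,
    )
    clinical = simulate_clinical(
        config, tumor_truth, target_signature=0, cancer_types=cancer
    )
    annotation = simulate_probe_annotation(
        probe_ids,
        seed=config.seed,
        hyper_idx=paired_truth.hyper_idx,
        hypo_idx=paired_truth.hypo_idx,
    )
    return StudyData(
        paired=paired,
        paired_truth=paired_truth,
        tumors=tumors,
        tumor_truth=tumor_truth,
        mutations=mut,
        expression=expr,
        clinical=clinical,
        annotation=annotation,
    )


@dataclass
class _ContaminationMode:
    """Mix tumor and normal means by (1 - purity) to test the purity filter."""

    config: SimulationConfig
    low_purity_frac: float = 0.3

    def apply(self, m: BetaMatrix, rng_seed: int = 0) -> BetaMatrix:
        rng = _rng(rng_seed, "paired")
        values = m.values.copy()
        sheet = m.samples.copy()
        pairs = m.pairs()
        n_low = int(round(self.low_purity_frac * len(pairs)))
        rows = rng.choice(len(pairs), size=n_low, replace=False)
        for r in rows:
            t, nrm = pairs.iloc[r]["tumor"], pairs.iloc[r]["normal"]
            purity = rng.uniform(0.2, 0.6)
            values[t] = purity * values[t] + (1 - purity) * values[nrm]
            sheet.loc[t, "purity"] = purity
        return BetaMatrix(values, sheet)


def contaminate(
    m: BetaMatrix,
    config: SimulationConfig,
    low_purity_frac: float = 0.3,
) -> BetaMatrix:
    """Return a copy with a fraction of tumors mixed toward their normals."""
    return _ContaminationMode(config, low_purity_frac).apply(
        m, rng_seed=config.seed
    )
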