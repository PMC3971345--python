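"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design the analysis is built for: a
small set of explanted lungs (COPD and donor), eight axial slices per
lung sampled apex to base, a per-slice emphysema severity measurement
(mean linear intercept, Lm, in micrometres), triplicate-probe miRNA
arrays with background controls, a gene expression matrix coupled to
the miRNAs through planted regulatory circuits, a multi-source target
prediction table, and a small two-group inhibitor (knockdown)
experiment. Ground truth is attached so recovery can be tested.

Generative model for miRNA feature m in sample s of patient j:

    y_ms = beta0_m + betaSlice_m * slice_s + betaLm_m * ln(Lm_s)
           + u_m,s [incoherent driver, if any] + b_mj + eps_ms

with b_mj ~ N(0, sigma_patient^2) and eps_ms ~ N(0, sigma_resid^2),
all on the log2 scale.  Circuit genes track their miRNA: coherent
circuits subtract a multiple of the centred miRNA value (direct
repression dominates, anti-correlation); incoherent circuits share a
latent per-sample driver with the miRNA (positive loading on both)
while keeping a weaker direct repressive term, yielding net positive
co-expression — the "common upstream regulator" mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "CohortData",
    "generate_cohort",
    "generate_lm_profile",
    "generate_probe_level",
    "generate_prediction_table",
    "generate_knockdown_experiment",
    "make_gene_sets",
]

# Lm scale conventions (micrometres): donors tight around 250 um, COPD
# higher and far more variable, drawn per slice on the ln scale.
DONOR_LN_LM = (np.log(250.0), 0.05)
COPD_LN_LM = (np.log(400.0), 0.35)
# Baselines are defined at a reference severity / mid-lung position, so
# planted effects perturb features around beta0 rather than shifting
# whole features out of the array's dynamic range.
LN_LM_REF = np.log(300.0)

# internal couplings / nuisance scales (log2 units)
MIRNA_BASELINE = (7.5, 1.0)
GENE_BASELINE = (8.0, 1.0)
GENE_SIGMA_PATIENT = 0.3
GENE_SIGMA_RESID = 0.3
COHERENT_COUPLING = 0.8
# Incoherent circuits: a shared upstream driver supplies this fraction of
# the miRNA's residual SD (total variance unchanged) and loads on the
# target gene with an amplified coefficient, overwhelming the weaker
# direct repression so the net miRNA-gene correlation is positive.
INCOHERENT_DRIVER_FRAC = 0.95
GENE_DRIVER_LOADING = 3.0
INCOHERENT_DIRECT = 0.1


@dataclass
class CohortConfig:
    """Study-design and effect-size knobs for cohort generation.

    Defaults are the desk-scale study conditions: 6 COPD + 2 donor
    lungs x 8 slices (64 samples), 400 miRNAs / 2,000 genes, ~15% of
    miRNAs truly Lm-associated and ~5% with an apex-to-base trend, and
    one hub miRNA (the knockdown candidate) with 60 planted targets.
    """

    n_copd_patients: int = 6
    n_donor_patients: int = 2
    slices_per_patient: int = 8
    n_mirna: int = 400
    n_gene: int = 2000
    frac_lm_mirna: float = 0.15
    beta_lm_range: tuple[float, float] = (0.5, 1.5)
    beta_slice: float = 0.1
    frac_slice_mirna: float = 0.05
    sigma_patient: float = 0.5
    sigma_resid: float = 0.3
    targets_per_mirna: int = 8
    frac_coherent: float = 0.35
    hub_targets: int = 60
    hub_frac_coherent: float = 1.0
    knockdown_fold_range: tuple[float, float] = (1.15, 1.4)
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_copd_patients,
            self.n_donor_patients,
            self.slices_per_patient,
            self.n_mirna,
            self.n_gene,
            self.targets_per_mirna,
        ]
        if any(int(c) < 1 or c != int(c) for c in counts):
            raise ValueError("all counts must be integers >= 1")
        for f in (self.frac_lm_mirna, self.frac_slice_mirna, self.frac_coherent,
                  self.hub_frac_coherent):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.sigma_patient < 0 or self.sigma_resid <= 0:
            raise ValueError("SDs must be positive")
        if self.knockdown_fold_range[0] <= 0:
            raise ValueError("fold-range lower bound must be > 0")


@dataclass
class GroundTruth:
    """Planted effects attached to a synthetic cohort."""

    lm_mirnas: dict[str, float] = field(default_factory=dict)
    slice_mirnas: dict[str, float] = field(default_factory=dict)
    circuits: list[tuple[str, str, str]] = field(default_factory=list)
    hub_mirna: str | None = None
    knockdown_targets: dict[str, float] = field(default_factory=dict)

    def circuit_type(self) -> dict[tuple[str, str], str]:
        return {(m, g): c for m, g, c in self.circuits}


@dataclass
class CohortData:
    """A generated cohort: metadata, latent matrices, probes, truth."""

    metadata: pd.DataFrame
    mirna: pd.DataFrame
    gene: pd.DataFrame
    probe_table: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


def generate_lm_profile(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample Lm (um) given COPD/donor group labels.

    Donor ln(Lm) is drawn from a tight distribution; COPD from a
    higher-mean, higher-variance one, independently per slice, so Lm
    varies within as well as between lungs. Always > 0 (log-normal).
    """
    groups = np.asarray(groups)
    lm = np.empty(groups.size)
    is_copd = groups == "COPD"
    lm[is_copd] = np.exp(rng.normal(*COPD_LN_LM, size=int(is_copd.sum())))
    lm[~is_copd] = np.exp(rng.normal(*DONOR_LN_LM, size=int((~is_copd).sum())))
    return lm


def _metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pid = 0
    for group, n in (("COPD", config.n_copd_patients), ("donor", config.n_donor_patients)):
        for _ in range(n):
            pid += 1
            for s in range(1, config.slices_per_patient + 1):
                rows.append(
                    {
                        "sample_id": f"P{pid:02d}_S{s}",
                        "patient_id": f"P{pid:02d}",
                        "group": group,
                        "slice": s,
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["lm_um"] = generate_lm_profile(meta["group"].to_numpy(), rng)
    return meta


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Generate a full cohort with planted ground truth.

    See the module docstring for the generative model. All randomness
    flows from ``config.seed``; identical config + seed reproduces the
    cohort bit for bit.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _metadata(config, rng)
    n_samples = len(meta)
    slice_v = meta["slice"].to_numpy(float)
    log_lm = np.log(meta["lm_um"].to_numpy(float))
    patients, codes = np.unique(meta["patient_id"].to_numpy(), return_inverse=True)

    mirna_ids = [f"miR-syn-{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_gene)]
    truth = GroundTruth()

    # --- planted fixed effects ----------------------------------------
    n_lm = int(round(config.frac_lm_mirna * config.n_mirna))
    lm_idx = rng.choice(config.n_mirna, size=n_lm, replace=False) if n_lm else np.array([], int)
    beta_lm = np.zeros(config.n_mirna)
    if n_lm:
        lo, hi = config.beta_lm_range
        mags = rng.uniform(lo, hi, size=n_lm)
        signs = rng.choice([-1.0, 1.0], size=n_lm)
        signs[0] = 1.0  # hub is upregulated with severity
        beta_lm[lm_idx] = mags * signs
        truth.hub_mirna = mirna_ids[lm_idx[0]]
        truth.lm_mirnas = {mirna_ids[i]: float(beta_lm[i]) for i in lm_idx}

    n_slice = int(round(config.frac_slice_mirna * config.n_mirna))
    slice_idx = rng.choice(config.n_mirna, size=n_slice, replace=False) if n_slice else np.array([], int)
    beta_slice = np.zeros(config.n_mirna)
    if n_slice:
        beta_slice[slice_idx] = config.beta_slice * rng.choice([-1.0, 1.0], size=n_slice)
        truth.slice_mirnas = {mirna_ids[i]: float(beta_slice[i]) for i in slice_idx}

    # --- circuits -----------------------------------------------------
    if n_lm:
        pool = rng.permutation(config.n_gene)
        cursor = 0
        circuit_rows: list[tuple[int, int, str]] = []
        for k, i in enumerate(lm_idx):
            n_t = config.hub_targets if k == 0 else config.targets_per_mirna
            frac_coh = config.hub_frac_coherent if k == 0 else config.frac_coherent
            if cursor + n_t > config.n_gene:
                raise ValueError("not enough genes for requested circuits")
            tgt = pool[cursor : cursor + n_t]
            cursor += n_t
            n_coh = int(round(frac_coh * n_t))
            for j, g in enumerate(tgt):
                circuit_rows.append((i, int(g), "coherent" if j < n_coh else "incoherent"))
        truth.circuits = [
            (mirna_ids[i], gene_ids[g], c) for i, g, c in circuit_rows
        ]
    else:
        circuit_rows = []
    driven = sorted({i for i, _, c in circuit_rows if c == "incoherent"})

    # --- miRNA matrix -------------------------------------------------
    # For miRNAs in incoherent circuits, a shared latent driver replaces
    # INCOHERENT_DRIVER_FRAC of the residual SD, leaving the miRNA's
    # total variance (and so the severity screen's operating point)
    # unchanged while giving targets a common upstream signal to share.
    beta0 = rng.normal(*MIRNA_BASELINE, size=config.n_mirna)
    b_pat = rng.normal(0.0, config.sigma_patient, size=(config.n_mirna, patients.size))
    sd_u = config.sigma_resid * INCOHERENT_DRIVER_FRAC
    sd_eps = np.full(config.n_mirna, config.sigma_resid)
    sd_eps[driven] = config.sigma_resid * np.sqrt(1.0 - INCOHERENT_DRIVER_FRAC**2)
    eps = rng.normal(0.0, 1.0, size=(config.n_mirna, n_samples)) * sd_eps[:, None]
    driver = {i: rng.normal(0.0, sd_u, size=n_samples) for i in driven}
    slice_c = slice_v - (config.slices_per_patient + 1) / 2.0
    M = (
        beta0[:, None]
        + beta_slice[:, None] * slice_c[None, :]
        + beta_lm[:, None] * (log_lm[None, :] - LN_LM_REF)
        + b_pat[:, codes]
        + eps
    )
    for i in driven:
        M[i] += driver[i]

    # --- gene matrix --------------------------------------------------
    g0 = rng.normal(*GENE_BASELINE, size=config.n_gene)
    g_pat = rng.normal(0.0, GENE_SIGMA_PATIENT, size=(config.n_gene, patients.size))
    g_eps = rng.normal(0.0, GENE_SIGMA_RESID, size=(config.n_gene, n_samples))
    G = g0[:, None] + g_pat[:, codes] + g_eps
    for i, g, c in circuit_rows:
        m_centered = M[i] - M[i].mean()
        if c == "coherent":
            G[g] -= COHERENT_COUPLING * m_centered
        else:
            G[g] += GENE_DRIVER_LOADING * driver[i] - INCOHERENT_DIRECT * m_centered

    # --- knockdown truth: coherent hub targets are derepressed --------
    if truth.hub_mirna is not None:
        lo, hi = config.knockdown_fold_range
        for m, g, c in truth.circuits:
            if m == truth.hub_mirna and c == "coherent":
                truth.knockdown_targets[g] = float(rng.uniform(lo, hi))

    mirna = pd.DataFrame(M, index=mirna_ids, columns=meta.index)
    gene = pd.DataFrame(G, index=gene_ids, columns=meta.index)
    probes = generate_probe_level(mirna, rng=rng)
    return CohortData(
        metadata=meta, mirna=mirna, gene=gene, probe_table=probes,
        truth=truth, config=config,
    )


def generate_probe_level(
    feature_matrix: pd.DataFrame,
    n_replicates: int = 3,
    background_params: tuple[float, float] = (3.0, 0.3),
    n_background: int = 50,
    dropout_rate: float = 0.02,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expand a log2 feature matrix into triplicate linear-scale probes.

    Each replicate intensity is 2^(value + N(0, noise_sd^2)) —
    multiplicative log-normal probe noise.  Background control probes
    are drawn from a low-intensity log-normal (``background_params`` on
    the log2 scale).  A ``dropout_rate`` fraction of replicates fail
    and fall to background level.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    F, S = feature_matrix.shape
    vals = feature_matrix.to_numpy(float)
    mu, sd = background_params
    rows = []
    ids = []
    for r in range(1, n_replicates + 1):
        inten = 2.0 ** (vals + rng.normal(0.0, noise_sd, size=(F, S)))
        failed = rng.random(size=(F, S)) < dropout_rate
        inten = np.where(failed, 2.0 ** rng.normal(mu, sd, size=(F, S)), inten)
        rows.append(inten)
        ids.extend(
            (f"{fid}_r{r}", fid, r, False) for fid in feature_matrix.index
        )
    bg = 2.0 ** rng.normal(mu, sd, size=(n_background, S))
    rows.append(bg)
    ids.extend((f"BG{i + 1:04d}", "", 0, True) for i in range(n_background))
    head = pd.DataFrame(ids, columns=["probe_id", "feature_id", "replicate", "is_background"])
    body = pd.DataFrame(np.vstack(rows), columns=list(feature_matrix.columns))
    return pd.concat([head, body], axis=1)


def generate_prediction_table(
    truth: GroundTruth,
    mirna_ids: list[str],
    gene_ids: list[str],
    n_sources: int = 5,
    source_sensitivity: float = 0.6,
    source_fpr: float = 0.0005,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a multi-algorithm target-prediction table.

    Each of ``n_sources`` independent sources flags every true circuit
    pair with probability ``source_sensitivity`` and every other pair
    with probability ``source_fpr``.  Rows with at least one flag are
    returned with per-source booleans and ``n_sources`` set counts.
    """
    if not 0 <= source_sensitivity <= 1 or not 0 <= source_fpr <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    true_pairs = {(m, g) for m, g, _ in truth.circuits}
    n_m, n_g = len(mirna_ids), len(gene_ids)
    is_true = np.zeros((n_m, n_g), dtype=bool)
    m_pos = {m: i for i, m in enumerate(mirna_ids)}
    g_pos = {g: i for i, g in enumerate(gene_ids)}
    for m, g in true_pairs:
        if m in m_pos and g in g_pos:
            is_true[m_pos[m], g_pos[g]] = True
    prob = np.where(is_true, source_sensitivity, source_fpr)
    flags = rng.random(size=(n_sources, n_m, n_g)) < prob[None]
    any_flag = flags.any(axis=0)
    mi, gi = np.nonzero(any_flag)
    table = pd.DataFrame(
        {
            "mirna_id": [mirna_ids[i] for i in mi],
            "gene_id": [gene_ids[j] for j in gi],
        }
    )
    for s in range(n_sources):
        table[f"source_{s + 1}"] = flags[s, mi, gi]
    table["n_sources"] = flags[:, mi, gi].sum(axis=0)
    return table


def generate_knockdown_experiment(
    gene_ids: list[str],
    targets: dict[str, float] | list[str],
    fold_range: tuple[float, float] = (1.15, 1.4),
    n_per_group: int = 3,
    baseline: np.ndarray | None = None,
    noise_sd: float = 0.15,
    var_prior_df: float = 10.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an inhibitor-vs-control array experiment.

    Planted targets are multiplied (on the linear scale) in the
    inhibitor group by a fold drawn uniformly from ``fold_range`` — the
    modest derepression range seen when a miRNA is inhibited — or by a
    pre-assigned per-gene fold when ``targets`` is a dict.  Gene-wise
    noise variances are drawn from a scaled inverse-chi-square prior
    (scale ``noise_sd``^2, ``var_prior_df`` df), the heterogeneity the
    empirical-Bayes moderated t is designed for.  Returns the log2
    expression matrix (genes x 2*n_per_group arrays) and group labels.
    """
    if fold_range[0] <= 0:
        raise ValueError("fold-range lower bound must be > 0")
    if len(targets) == 0:
        raise ValueError("targets must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    n_gene = len(gene_ids)
    if baseline is None:
        baseline = rng.normal(*GENE_BASELINE, size=n_gene)
    folds = np.zeros(n_gene)
    pos = {g: i for i, g in enumerate(gene_ids)}
    if isinstance(targets, dict):
        for g, f in targets.items():
            if g in pos:
                folds[pos[g]] = np.log2(f)
    else:
        for g in targets:
            if g in pos:
                folds[pos[g]] = np.log2(rng.uniform(*fold_range))
    cols = [f"ctrl_{i + 1}" for i in range(n_per_group)] + [
        f"inh_{i + 1}" for i in range(n_per_group)
    ]
    shift = np.concatenate(
        [np.zeros(n_per_group), np.ones(n_per_group)]
    )  # inhibitor arrays carry the derepression
    sd_g = noise_sd * np.sqrt(var_prior_df / rng.chisquare(var_prior_df, size=n_gene))
    expr = (
        baseline[:, None]
        + folds[:, None] * shift[None, :]
        + sd_g[:, None] * rng.normal(0.0, 1.0, size=(n_gene, 2 * n_per_group))
    )
    groups = pd.Series(
        ["control"] * n_per_group + ["inhibitor"] * n_per_group, index=cols
    )
    return pd.DataFrame(expr, index=gene_ids, columns=cols), groups


def make_gene_sets(
    truth: GroundTruth,
    gene_ids: list[str],
    n_planted: int = 5,
    n_null: int = 35,
    planted_size: int = 25,
    planted_frac_target: float = 0.6,
    null_size_range: tuple[int, int] = (15, 60),
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Toy pathway collection: planted sets enriched in hub targets.

    Planted sets draw ``planted_frac_target`` of their members from the
    hub miRNA's coherent-circuit targets (the genes both repressed in
    tissue and derepressed on knockdown), the rest at random; null sets
    are random draws. Emulates pathway-structured regulation without
    any real pathway database.
    """
    rng = np.random.default_rng() if rng is None else rng
    hub_targets = [
        g for m, g, c in truth.circuits
        if m == truth.hub_mirna and c == "coherent" and g in set(gene_ids)
    ]
    sets: dict[str, list[str]] = {}
    for i in range(n_planted):
        k_t = min(int(round(planted_frac_target * planted_size)), len(hub_targets))
        members = list(rng.choice(hub_targets, size=k_t, replace=False))
        filler = [g for g in rng.choice(gene_ids, size=planted_size, replace=False)
                  if g not in members][: planted_size - k_t]
        sets[f"PLANTED_PATHWAY_{i + 1}"] = members + filler
    for i in range(n_null):
        size = int(rng.integers(null_size_range[0], null_size_range[1] + 1))
        sets[f"NULL_PATHWAY_{i + 1}"] = list(
            rng.choice(gene_ids, size=size, replace=False)
        )
    return sets
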