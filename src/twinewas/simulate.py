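"""Synthetic twin-cohort generator.

Produces a complete dataset — sample sheet, genotype dosages, methylation
betas, phenotypes, white-blood-cell counts and expression — with the
statistical structure the downstream analyses assume:

* MZ co-twins share all genetic effects, DZ co-twins share each allele
  with probability 1/2 (per-SNP parental transmission, not a global 0.5
  correlation);
* methylation betas arise as the inverse logit of Gaussian liabilities
  (additive genetic + shared family environment + cis-SNP dosage + age
  + chip + co-methylation field + iid noise), preserving the additive
  covariance structure twin models assume while bounding to [0, 1];
* co-methylation follows an Ornstein-Uhlenbeck field along the genome,
  so the correlation between two probes decays as exp(-distance/scale);
* age effects are predominantly hyper-methylating (``hyper_fraction``);
* phenotypes follow trait = intercept + age-slope x age + family effect
  + noise with completely-at-random missingness at configured rates.

Every generator is a pure function of (config, seed); a ground-truth
sidecar table records each probe's class and true effects so that the
sensitivity and FDR of every downstream scan are measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    DatasetBundle,
    GenotypeMatrix,
    MethylationMatrix,
    PhenotypeTable,
    TwinCohort,
)

__all__ = [
    "SimulationConfig",
    "TABLE1_TRAITS",
    "GWAS_TRAITS",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_phenotypes",
    "simulate_wbc",
    "simulate_expression",
    "simulate_dataset",
]

# trait -> (age slope per year, observed-data fraction, residual SD, intercept)
# Slopes and data fractions follow the study's phenotype table; residual SDs
# and intercepts are chosen to give realistic trait scales (see docs).
TABLE1_TRAITS: dict[str, tuple[float, float, float, float]] = {
    "Telomere": (-0.030, 0.622, 0.60, 8.5),
    "SBP": (0.663, 1.000, 15.0, 85.0),
    "DBP": (-0.019, 1.000, 10.0, 80.0),
    "FEV1": (-0.028, 0.977, 0.45, 3.8),
    "FVC": (-0.028, 0.977, 0.50, 4.8),
    "Grip": (-0.451, 0.640, 7.0, 55.0),
    "BMD": (-0.005, 0.867, 0.12, 1.30),
    "DHEAS": (-0.023, 0.994, 1.20, 8.0),
    "Cholesterol": (0.052, 0.971, 1.00, 3.5),
    "HDL": (0.016, 0.971, 0.40, 1.0),
    "LDL": (0.018, 0.948, 0.90, 2.5),
    "Albumin": (-0.102, 0.919, 2.50, 48.0),
    "Creatinine": (0.120, 0.860, 10.0, 70.0),
    "MLONG": (2.3e-6, 0.738, 8.0, 78.0),
    "PLONG": (4.1e-6, 0.733, 8.0, 75.0),
    "MREPROD": (6.3e-6, 0.808, 5.0, 28.0),
    "PREPROD": (6.2e-6, 0.820, 5.0, 30.0),
}

#: the 12 phenotypes entered into GWAS / MZ-discordance analyses
#: (parental longevity and age-at-reproduction excluded; lung function
#: contributes FEV1 and FVC as separate traits)
GWAS_TRAITS = (
    "Telomere",
    "SBP",
    "DBP",
    "FEV1",
    "FVC",
    "Grip",
    "BMD",
    "DHEAS",
    "Cholesterol",
    "HDL",
    "LDL",
    "Albumin",
    "Creatinine",
)

PROBE_CLASSES = ("heritable", "meqtl", "age", "null")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    # cohort composition
    n_mz_pairs: int = 33
    n_dz_pairs: int = 43
    n_singletons: int = 20
    age_range: tuple[float, float] = (32.0, 80.0)
    chip_size: int = 12
    n_batches: int = 2
    batch1_fraction: float = 93.0 / 172.0
    randomize_chips: bool = False
    seed: int = 0

    # probe panel
    n_probes: int = 500
    frac_heritable: float = 0.25
    frac_meqtl: float = 0.10
    frac_age: float = 0.10
    frac_x: float = 0.0
    frac_nonunique: float = 0.0
    missing_beta_rate: float = 0.0
    island_prob: float = 0.42
    island_prob_age: float = 0.72

    probe_spacing_scale: float = 1.0  # multiplies inter-probe gap draws

    # genotypes
    snps_per_probe: int = 2
    maf_range: tuple[float, float] = (0.10, 0.50)
    cis_window: int = 100_000

    # liability model (all SDs on the latent logit scale)
    mean_h2: float = 0.40
    meqtl_beta: float = 0.8  # per-allele effect in residual-liability-SD units
    age_effect: float = 0.012  # liability per year at age-class probes
    hyper_fraction: float = 0.98
    family_sd: float = 0.10
    chip_sd: float = 0.06
    chip_position_slope: float = 0.0
    block_bp: float = 2000.0  # co-methylation decay scale
    comethylation_sd: float = 0.12
    noise_sd: float = 0.25

    # phenotypes
    trait_params: dict = field(default_factory=lambda: dict(TABLE1_TRAITS))
    pheno_family_sd_frac: float = 0.4
    couple_probes: tuple = ()  # probe indices coupled into couple_trait
    couple_trait: str | None = None
    couple_strength: float = 0.0  # trait-residual-SD units per liability SD

    # white blood cells
    wbc_dirichlet: tuple = (54.0, 3.0, 7.0, 36.0)
    wbc_total_mean: float = 7.0
    wbc_total_sd: float = 1.6
    lymph_probes: tuple = ()  # probe indices coupled to lymphocyte counts
    lymph_coupling: float = 0.0

    # expression
    expression_coupling: float = 5.0  # expression units per unit beta
    expression_coupling_other: float = 5.0
    expression_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.frac_heritable + self.frac_meqtl + self.frac_age > 1 + 1e-9:
            raise ValueError("probe class fractions must sum to <= 1")
        for name in ("family_sd", "chip_sd", "comethylation_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.mean_h2 < 1:
            raise ValueError("mean_h2 must lie in [0, 1)")
        if self.block_bp <= 0:
            raise ValueError("co-methylation block size must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons

    def residual_liability_var(self) -> float:
        """Non-genetic per-individual liability variance (family + co-methylation + noise + chip)."""
        return (
            self.family_sd**2
            + self.comethylation_sd**2
            + self.noise_sd**2
            + self.chip_sd**2
        )


def _rng(cfg: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), salt]))


def simulate_cohort(cfg: SimulationConfig) -> TwinCohort:
    """Sample sheet: families, zygosity, shared twin ages, chips, batches."""
    if cfg.n_individuals == 0:
        raise ValueError("cohort must contain at least one individual")
    rng = _rng(cfg, 1)
    blocks = []
    fam = 0
    for zyg, n_pairs in (("MZ", cfg.n_mz_pairs), ("DZ", cfg.n_dz_pairs)):
        for _ in range(n_pairs):
            fam += 1
            age = rng.uniform(*cfg.age_range)
            blocks.append([(f"I{fam:04d}{k}", f"F{fam:04d}", zyg, age) for k in (1, 2)])
    for _ in range(cfg.n_singletons):
        fam += 1
        age = rng.uniform(*cfg.age_range)
        blocks.append([(f"I{fam:04d}1", f"F{fam:04d}", "singleton", age)])
    # family blocks in shuffled order (co-twins adjacent) so chips and
    # batches each contain a mixture of zygosities
    blocks = [blocks[i] for i in rng.permutation(len(blocks))]
    rows = [r for blk in blocks for r in blk]
    df = pd.DataFrame(rows, columns=["individual_id", "family_id", "zygosity", "age"])
    df["sex"] = "F"
    order = np.arange(len(df))
    if cfg.randomize_chips:
        order = rng.permutation(order)
    chip_no = np.empty(len(df), dtype=int)
    chip_pos = np.empty(len(df), dtype=int)
    chip_no[order] = np.arange(len(df)) // cfg.chip_size
    chip_pos[order] = np.arange(len(df)) % cfg.chip_size + 1
    df["chip_id"] = [f"chip{c:03d}" for c in chip_no]
    df["chip_position"] = chip_pos
    n_b1 = int(round(cfg.batch1_fraction * len(df))) if cfg.n_batches > 1 else len(df)
    df["batch_id"] = ["batch1" if i < n_b1 else "batch2" for i in range(len(df))]
    return TwinCohort(df.set_index("individual_id"))


def _probe_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe positions/classes and the SNP map placed around them."""
    n = cfg.n_probes
    n_x = int(round(cfg.frac_x * n))
    classes = np.full(n, "null", dtype=object)
    n_h = int(round(cfg.frac_heritable * n))
    n_q = int(round(cfg.frac_meqtl * n))
    n_a = int(round(cfg.frac_age * n))
    auto_idx = rng.permutation(n - n_x)  # X probes (last n_x) stay class null
    classes[auto_idx[:n_h]] = "heritable"
    classes[auto_idx[n_h : n_h + n_q]] = "meqtl"
    classes[auto_idx[n_h + n_q : n_h + n_q + n_a]] = "age"

    # cluster probes so that nearby pairs at a range of distances exist
    chroms, poss = [], []
    chrom, pos = 1, 1_000_000
    for i in range(n - n_x):
        if i > 0:
            if rng.random() < 0.55:
                gap = int(rng.exponential(700)) + 50
            else:
                gap = int(rng.exponential(60_000)) + 5_000
            pos += int(gap * cfg.probe_spacing_scale)
        if pos > 120_000_000 or (i > 0 and rng.random() < 0.002):
            chrom = min(chrom + 1, 22)
            pos = 1_000_000
        chroms.append(str(chrom))
        poss.append(pos)
    for i in range(n_x):
        chroms.append("X")
        poss.append(1_000_000 + i * 25_000)

    island = np.where(
        classes == "age",
        rng.random(n) < cfg.island_prob_age,
        rng.random(n) < cfg.island_prob,
    )
    unique = rng.random(n) >= cfg.frac_nonunique
    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "nearest_gene": [f"GENE{i // 2:05d}" for i in range(n)],
            "tss_distance": rng.integers(-2800, 2801, size=n),
            "cpg_island": island,
            "unique": unique,
        },
        index=pd.Index([f"cg{i:07d}" for i in range(n)], name="probe_id"),
    )
    ann["class"] = classes

    # SNPs: for meqtl probes one causal SNP close by, plus background SNPs
    snp_rows = []
    k = 0
    for i in range(n - n_x):
        for j in range(cfg.snps_per_probe):
            if classes[i] == "meqtl" and j == 0:
                offset = int(rng.integers(-cfg.cis_window // 4, cfg.cis_window // 4))
            else:
                offset = int(rng.integers(-int(0.9 * cfg.cis_window), int(0.9 * cfg.cis_window)))
            snp_rows.append(
                (
                    f"rs{k:07d}",
                    chroms[i],
                    max(poss[i] + offset, 1),
                    float(rng.uniform(*cfg.maf_range)),
                    ann.index[i] if (classes[i] == "meqtl" and j == 0) else "",
                )
            )
            k += 1
    snp_map = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "maf", "causal_for"]
    ).set_index("snp_id")
    return ann, snp_map


def simulate_genotypes(cfg: SimulationConfig, cohort: TwinCohort, snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """SNP dosages: Hardy-Weinberg founders, Mendelian sharing within pairs."""
    rng = _rng(cfg, 2)
    if snp_map is None:
        snp_map = _probe_annotation(cfg, _rng(cfg, 3))[1]
    maf = snp_map["maf"].to_numpy()
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("MAF must lie in (0, 0.5]")
    S = len(snp_map)
    samples = cohort.samples
    dosage = np.zeros((S, len(samples)))
    pos = {s: i for i, s in enumerate(samples.index)}
    for fam, grp in samples.groupby("family_id", sort=True):
        # four parental alleles per SNP
        par = rng.random((S, 4)) < maf[:, None]
        ids = sorted(grp.index)
        if len(ids) == 2 and grp["zygosity"].iloc[0] == "MZ":
            child = par[:, 0].astype(float) + par[:, 2].astype(float)
            dosage[:, pos[ids[0]]] = child
            dosage[:, pos[ids[1]]] = child
        elif len(ids) == 2:
            for s in ids:
                pick_p = rng.integers(0, 2, size=S)
                pick_m = rng.integers(0, 2, size=S) + 2
                dosage[:, pos[s]] = (
                    par[np.arange(S), pick_p].astype(float)
                    + par[np.arange(S), pick_m].astype(float)
                )
        else:
            dosage[:, pos[ids[0]]] = par[:, 0].astype(float) + par[:, 2].astype(float)
    dos = pd.DataFrame(dosage, index=snp_map.index, columns=samples.index)
    return GenotypeMatrix(dos, snp_map[["chrom", "pos", "maf"]].copy())


def _liabilities(
    cfg: SimulationConfig,
    cohort: TwinCohort,
    genos: GenotypeMatrix | None,
    ann: pd.DataFrame,
    snp_map: pd.DataFrame,
    wbc: pd.DataFrame | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    samples = cohort.samples
    n_ind = len(samples)
    n = len(ann)
    classes = ann["class"].to_numpy()
    if cfg.frac_meqtl > 0 and genos is None:
        raise ValueError("genotypes required when the meqtl probe class is present")

    fam_codes, fam_idx = np.unique(samples["family_id"], return_inverse=True)
    is_mz = samples["zygosity"].to_numpy() == "MZ"
    age = samples["age"].to_numpy(dtype=float)
    age_c = age - np.mean(cfg.age_range)

    resid_var = cfg.residual_liability_var()
    truth = pd.DataFrame(index=ann.index)
    truth["class"] = classes
    truth["true_h2"] = 0.0
    truth["age_slope"] = 0.0
    truth["causal_snp"] = ""
    truth["meqtl_beta"] = 0.0

    # probe-level truth (baselines, effect signs) is salted separately from
    # the per-individual noise so that cohorts of different size drawn from
    # the same config share the same probe effects (replication designs)
    rng_probe = _rng(cfg, 8)

    # baseline methylation level: mostly un-methylated promoters
    low = rng_probe.random(n) < 0.7
    mu = np.where(
        low,
        rng_probe.normal(np.log(0.18 / 0.82), 0.45, size=n),
        rng_probe.normal(0.0, 0.7, size=n),
    )
    mu = np.clip(mu, -2.4, 2.4)

    L = np.tile(mu[:, None], (1, n_ind))

    # additive genetic term: shared fully by MZ, half by DZ (two half-effects)
    her = classes == "heritable"
    if her.any() and cfg.mean_h2 > 0:
        var_g = cfg.mean_h2 / (1.0 - cfg.mean_h2) * resid_var
        sd_half = np.sqrt(var_g / 2.0)
        shared = rng.normal(0.0, sd_half, size=(int(her.sum()), len(fam_codes)))[:, fam_idx]
        own = rng.normal(0.0, sd_half, size=(int(her.sum()), n_ind))
        # MZ co-twins share the 'own' half too: copy first twin's draw
        first_of_pair: dict[int, int] = {}
        for j in range(n_ind):
            f = fam_idx[j]
            if is_mz[j]:
                if f in first_of_pair:
                    own[:, j] = own[:, first_of_pair[f]]
                else:
                    first_of_pair[f] = j
        L[her] += shared + own
        truth.loc[her, "true_h2"] = cfg.mean_h2

    # cis-meQTL term
    qtl = classes == "meqtl"
    if qtl.any():
        beta_allele = cfg.meqtl_beta * np.sqrt(resid_var)
        causal = snp_map.loc[snp_map["causal_for"] != ""]
        snp_for_probe = {p: s for s, p in causal["causal_for"].items()}
        dos = genos.dosages
        for i in np.where(qtl)[0]:
            pid = ann.index[i]
            sid = snp_for_probe.get(pid)
            if sid is None:
                continue
            d = dos.loc[sid, samples.index].to_numpy(dtype=float)
            L[i] += beta_allele * (d - d.mean())
            truth.iloc[i, truth.columns.get_loc("causal_snp")] = sid
            truth.iloc[i, truth.columns.get_loc("meqtl_beta")] = beta_allele

    # age term, predominantly hyper-methylating
    agecls = classes == "age"
    if agecls.any():
        sign = np.where(rng_probe.random(int(agecls.sum())) < cfg.hyper_fraction, 1.0, -1.0)
        slopes = sign * cfg.age_effect
        L[agecls] += slopes[:, None] * age_c[None, :]
        truth.loc[agecls, "age_slope"] = slopes

    # shared family environment
    if cfg.family_sd > 0:
        L += cfg.family_sd * rng.normal(size=(n, len(fam_codes)))[:, fam_idx]

    # chip and chip-order effects
    chip_codes, chip_idx = np.unique(samples["chip_id"], return_inverse=True)
    if cfg.chip_sd > 0:
        L += cfg.chip_sd * rng.normal(size=(n, len(chip_codes)))[:, chip_idx]
    if cfg.chip_position_slope != 0.0:
        L += cfg.chip_position_slope * samples["chip_position"].to_numpy(dtype=float)[None, :]

    # co-methylation: Ornstein-Uhlenbeck field along each chromosome so
    # corr(probe_i, probe_j) = exp(-|pos_i - pos_j| / block_bp)
    if cfg.comethylation_sd > 0:
        order = np.lexsort((ann["pos"].to_numpy(), ann["chrom"].to_numpy()))
        u = np.empty((n, n_ind))
        prev_chrom, prev_pos = None, 0
        z = rng.normal(size=(n, n_ind))
        for rank, i in enumerate(order):
            ch, p = ann["chrom"].iloc[i], int(ann["pos"].iloc[i])
            if ch != prev_chrom:
                u[i] = z[rank]
            else:
                phi = np.exp(-(p - prev_pos) / cfg.block_bp)
                u[i] = phi * u[prev_i] + np.sqrt(1 - phi**2) * z[rank]
            prev_chrom, prev_pos, prev_i = ch, p, i
        L += cfg.comethylation_sd * u

    # lymphocyte-count coupling
    if len(cfg.lymph_probes) and cfg.lymph_coupling != 0.0:
        if wbc is None:
            raise ValueError("wbc table required for lymphocyte-coupled probes")
        ly = wbc.loc[samples.index, "lymphocytes"].to_numpy(dtype=float)
        z_ly = (ly - ly.mean()) / ly.std()
        for i in cfg.lymph_probes:
            L[int(i)] += cfg.lymph_coupling * z_ly
    truth["lymph_coupled"] = False
    if len(cfg.lymph_probes):
        truth.iloc[list(cfg.lymph_probes), truth.columns.get_loc("lymph_coupled")] = True

    # iid noise
    if cfg.noise_sd > 0:
        L += cfg.noise_sd * rng.normal(size=(n, n_ind))
    return L, truth


def simulate_methylation(
    cfg: SimulationConfig,
    cohort: TwinCohort,
    genos: GenotypeMatrix | None = None,
    wbc: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Beta matrix plus ground-truth sidecar (probe class, true effects)."""
    ann, snp_map = _probe_annotation(cfg, _rng(cfg, 3))
    rng = _rng(cfg, 4)
    L, truth = _liabilities(cfg, cohort, genos, ann, snp_map, wbc, rng)
    betas = 1.0 / (1.0 + np.exp(-L))
    if cfg.missing_beta_rate > 0:
        mask = rng.random(betas.shape) < cfg.missing_beta_rate
        betas = np.where(mask, np.nan, betas)
    bdf = pd.DataFrame(betas, index=ann.index, columns=cohort.samples.index)
    m = MethylationMatrix(bdf, ann.drop(columns=["class"]))
    return m, truth


def simulate_phenotypes(
    cfg: SimulationConfig,
    cohort: TwinCohort,
    liabilities: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """Trait table with age slopes, family effects and MCAR missingness.

    ``liabilities`` (probes x individuals, e.g. standardized beta values
    or the truth-scale liabilities) enables coupling designated probes
    into ``couple_trait`` for mediation / MZ-discordance architectures.
    """
    rng = _rng(cfg, 5)
    samples = cohort.samples
    age = samples["age"].to_numpy(dtype=float)
    fam_codes, fam_idx = np.unique(samples["family_id"], return_inverse=True)
    cols = {}
    for trait, (slope, data_frac, resid_sd, intercept) in cfg.trait_params.items():
        fam_eff = cfg.pheno_family_sd_frac * resid_sd * rng.normal(size=len(fam_codes))
        y = intercept + slope * age + fam_eff[fam_idx] + resid_sd * rng.normal(size=len(samples))
        if (
            cfg.couple_trait == trait
            and len(cfg.couple_probes)
            and cfg.couple_strength != 0.0
        ):
            if liabilities is None:
                raise ValueError("probe liabilities required for trait coupling")
            for i in cfg.couple_probes:
                lv = liabilities.iloc[int(i)].loc[samples.index].to_numpy(dtype=float)
                z = (lv - lv.mean()) / lv.std()
                y = y + cfg.couple_strength * resid_sd * z
        miss = rng.random(len(samples)) >= data_frac
        y = np.where(miss, np.nan, y)
        cols[trait] = y
    unknown = [t for t in cols if t not in TABLE1_TRAITS and t not in cfg.trait_params]
    if unknown:
        raise ValueError(f"unknown traits: {unknown}")
    return PhenotypeTable(pd.DataFrame(cols, index=samples.index))


def simulate_wbc(cfg: SimulationConfig, cohort: TwinCohort) -> pd.DataFrame:
    """White-blood-cell sub-type counts: Dirichlet proportions x total count."""
    rng = _rng(cfg, 6)
    n = len(cohort.samples)
    props = rng.dirichlet(np.asarray(cfg.wbc_dirichlet, dtype=float), size=n)
    total = np.exp(rng.normal(np.log(cfg.wbc_total_mean), cfg.wbc_total_sd / cfg.wbc_total_mean, size=n))
    counts = props * total[:, None]
    return pd.DataFrame(
        counts,
        index=cohort.samples.index,
        columns=["neutrophils", "eosinophils", "monocytes", "lymphocytes"],
    )


def simulate_expression(cfg: SimulationConfig, m: MethylationMatrix, truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expression (genes x individuals), negatively coupled to methylation."""
    rng = _rng(cfg, 7)
    gene_meth = m.betas.groupby(m.annotation["nearest_gene"]).mean()
    coupling = pd.Series(cfg.expression_coupling_other, index=gene_meth.index)
    if truth is not None:
        dmr_genes = m.annotation.loc[truth["class"] == "age", "nearest_gene"].unique()
        coupling.loc[coupling.index.isin(dmr_genes)] = cfg.expression_coupling
    baseline = rng.normal(8.0, 1.0, size=len(gene_meth))
    noise = rng.normal(0.0, cfg.expression_noise_sd, size=gene_meth.shape)
    expr = baseline[:, None] - coupling.to_numpy()[:, None] * gene_meth.to_numpy() + noise
    return pd.DataFrame(expr, index=gene_meth.index, columns=gene_meth.columns)


def simulate_dataset(cfg: SimulationConfig) -> DatasetBundle:
    """Generate the full aligned bundle (the study in synthetic form)."""
    cohort = simulate_cohort(cfg)
    _, snp_map = _probe_annotation(cfg, _rng(cfg, 3))
    genos = simulate_genotypes(cfg, cohort, snp_map)
    wbc = simulate_wbc(cfg, cohort)
    m, truth = simulate_methylation(cfg, cohort, genos, wbc)
    # couple phenotypes to the *beta* signal of designated probes
    phenos = simulate_phenotypes(cfg, cohort, liabilities=m.betas)
    expr = simulate_expression(cfg, m, truth)
    return DatasetBundle(
        methylation=m,
        cohort=cohort,
        genotypes=genos,
        phenotypes=phenos,
        expression=expr,
        truth=truth,
        wbc=wbc,
    )
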