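"""Synthetic GWAS summary statistics with known causal structure.

The generator works directly on the summary-statistic scale (two-sample MR
consumes nothing else): for each instrument SNP j a true exposure effect
gamma_j ~ N(0, gamma_sd) is resampled until it is genome-wide significant at
its sampled SE, the observed exposure effect is gamma_j plus sampling noise
(redrawn, bounded, until the observed p is also < 5e-8, so generated
instruments always pass the significance screen), and the outcome effect is

    beta_Y,j ~ Normal(theta * gamma_j + alpha_j, se_Y,j)

where theta is the true causal effect and alpha_j the direct (pleiotropic)
path: zero for valid instruments, Normal(0, sd) under balanced pleiotropy,
Normal(mean, sd) under directional pleiotropy (optionally only on a fraction
of instruments), or a fixed large effect for designated outliers.
Non-instrument SNPs are pure noise on both sides. Alleles, effect-allele
frequencies, palindromic and strand-flipped records, an LD dosage panel
(block-correlated via shared latent factors), and confounder annotations are
generated so that every screening stage of the pipeline has labeled work to
do, and a ``truth`` table records every SNP's role for exact attrition
accounting. All outputs are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, GenerationError
from .instruments import DEFAULT_CONFOUNDER_TRAITS, LdReference
from .sumstats import SumstatsTable

#: |z| needed for two-sided p < 5e-8.
GWS_Z = float(stats.norm.isf(2.5e-8))
GWS_P = 5e-8

_ORDERED_ALLELES = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                    ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
_PALINDROMIC_ALLELES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class NoPleiotropy:
    kind: str = "none"


@dataclass(frozen=True)
class BalancedPleiotropy:
    sd: float
    frac: float = 1.0
    kind: str = "balanced"


@dataclass(frozen=True)
class DirectionalPleiotropy:
    mean: float
    sd: float
    frac: float = 1.0
    kind: str = "directional"


@dataclass(frozen=True)
class OutlierPleiotropy:
    count: int
    effect: float
    kind: str = "outlier"


@dataclass
class SimulationConfig:
    """Generative settings for one exposure/outcome trait pair.

    Defaults describe a well-powered GWAS pair: 200 SNPs of which 30 are
    true instruments, per-SNP standard errors around 0.02 (large-biobank
    scale), instrument effects with SD 0.15 (comfortably genome-wide
    significant at those SEs), common variants (MAF 0.05-0.5), and no
    pleiotropy, palindromes, strand flips, LD, or confounders unless asked.
    """

    n_snp: int = 200
    n_instrument: int = 30
    theta: float = 0.0
    gamma_sd: float = 0.15
    se_exp_range: tuple[float, float] = (0.015, 0.025)
    se_out_range: tuple[float, float] = (0.015, 0.025)
    pleiotropy: object = field(default_factory=NoPleiotropy)
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.0
    frac_strand_flipped: float = 0.0
    ld_blocks: list[tuple[int, float]] | None = None
    n_confounder_snps: int = 0
    n_panel_samples: int = 500
    gwas_n: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_instrument <= self.n_snp):
            raise ConfigurationError("need 0 <= n_instrument <= n_snp")
        for frac in (self.frac_palindromic, self.frac_strand_flipped):
            if not (0 <= frac <= 1):
                raise ConfigurationError("fractions must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_confounder_snps > self.n_snp:
            raise ConfigurationError("n_confounder_snps exceeds n_snp")
        if self.ld_blocks:
            for size, r in self.ld_blocks:
                if size > self.n_snp:
                    raise ConfigurationError("LD block larger than n_snp")
                if not (0 <= r <= 1):
                    raise ConfigurationError("within-block r must be in [0, 1]")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _block_sizes(config: SimulationConfig) -> list[tuple[int, float]]:
    blocks = list(config.ld_blocks or [])
    assigned = sum(size for size, _ in blocks)
    if assigned > config.n_snp:
        raise ConfigurationError("LD blocks cover more SNPs than n_snp")
    blocks.extend((1, 0.0) for _ in range(config.n_snp - assigned))
    return blocks


def snp_map(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic shared SNP map: rsid, chrom, pos, alleles, eaf, block.

    Blocks land on chromosomes 1-22 in turn; block start positions are
    2.5 Mb apart (outside any 1 Mb clump window) and SNPs within a block sit
    5 kb apart (well inside it). Both tables and the LD panel derive from
    this one map, so positions and alleles always agree.
    """
    rng = _rng(config, 0)
    blocks = _block_sizes(config)
    rows = []
    chrom_pos = {str(c): 1_000_000 for c in range(1, 23)}
    snp_idx = 0
    for block_id, (size, r) in enumerate(blocks):
        chrom = str(block_id % 22 + 1)
        start = chrom_pos[chrom]
        for i in range(size):
            rows.append({"rsid": f"rs{snp_idx + 1}", "chrom": chrom,
                         "pos": start + i * 5_000, "block": block_id,
                         "block_r": r})
            snp_idx += 1
        chrom_pos[chrom] = start + 2_500_000
    df = pd.DataFrame(rows)

    palindromic = rng.random(len(df)) < config.frac_palindromic
    ea, oa = [], []
    for is_pal in palindromic:
        pool = _PALINDROMIC_ALLELES if is_pal else _ORDERED_ALLELES
        a1, a2 = pool[rng.integers(len(pool))]
        ea.append(a1)
        oa.append(a2)
    df["effect_allele"] = ea
    df["other_allele"] = oa
    df["is_palindromic"] = palindromic

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, len(df))
    flip = rng.random(len(df)) < 0.5
    df["eaf"] = np.where(flip, 1.0 - maf, maf)
    return df


def _resample_until(rng, draw, accept, what, max_rounds: int = 1000):
    """Vectorized rejection sampling: redraw failing entries until all pass."""
    values = draw(rng)
    pending = ~accept(values)
    rounds = 0
    while pending.any():
        rounds += 1
        if rounds > max_rounds:
            raise GenerationError(
                f"could not satisfy {what} within {max_rounds} redraws; "
                "the configured SE/effect-size ranges make genome-wide "
                "significance unreachable")
        fresh = draw(rng)
        values = np.where(pending, fresh, values)
        pending = ~accept(values)
    return values


def _significant_gammas(rng, se, gamma_sd):
    """True effects resampled until genome-wide significant at their SE."""
    return _resample_until(
        rng,
        draw=lambda r: r.normal(0.0, gamma_sd, size=len(se)),
        accept=lambda g: np.abs(g) / se > GWS_Z,
        what="true-effect significance")


def _significant_observed(rng, gamma, se):
    """Observed effects redrawn until the observed p is also < 5e-8."""
    return _resample_until(
        rng,
        draw=lambda r: gamma + se * r.standard_normal(len(se)),
        accept=lambda b: np.abs(b) / se > GWS_Z,
        what="observed-effect significance")


def _two_sided_p(beta, se):
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.nextafter(0, 1))   # keep p in (0, 1]


def _pleiotropy_effects(rng, config: SimulationConfig, inst_idx: np.ndarray,
                        gamma: np.ndarray, n_snp: int):
    """Per-SNP direct outcome effects alpha and the outlier label.

    Directional pleiotropy and outlier effects are expressed on the
    exposure-increasing allele orientation (multiplied by sign(gamma)), the
    convention under which a common direct-effect mean biases every Wald
    ratio the same way; balanced pleiotropy is sign-symmetric anyway.
    """
    alpha = np.zeros(n_snp)
    is_outlier = np.zeros(n_snp, dtype=bool)
    model = config.pleiotropy
    if isinstance(model, NoPleiotropy) or len(inst_idx) == 0:
        return alpha, is_outlier
    orient = np.where(gamma < 0, -1.0, 1.0)
    if isinstance(model, (BalancedPleiotropy, DirectionalPleiotropy)):
        n_bad = int(round(model.frac * len(inst_idx)))
        bad = rng.choice(inst_idx, size=n_bad, replace=False)
        mean = model.mean if isinstance(model, DirectionalPleiotropy) else 0.0
        alpha[bad] = orient[bad] * rng.normal(mean, model.sd, size=n_bad)
        return alpha, is_outlier
    if isinstance(model, OutlierPleiotropy):
        n_out = min(model.count, len(inst_idx))
        bad = rng.choice(inst_idx, size=n_out, replace=False)
        alpha[bad] = orient[bad] * model.effect
        is_outlier[bad] = True
        return alpha, is_outlier
    raise ConfigurationError(f"unknown pleiotropy model {model!r}")


def simulate_pair(config: SimulationConfig):
    """Generate one (exposure, outcome, truth) triple.

    Returns ``(exposure: SumstatsTable, outcome: SumstatsTable,
    truth: DataFrame)`` where ``truth`` labels every SNP (is_instrument,
    is_confounder, is_outlier, is_palindromic, is_strand_flipped) and holds
    its true effects gamma (on the exposure) and alpha (direct on the
    outcome).
    """
    smap = snp_map(config)
    rng = _rng(config, 1)
    n = config.n_snp

    perm = rng.permutation(n)
    inst_idx = np.sort(perm[:config.n_instrument])
    conf_idx = np.sort(perm[config.n_instrument:
                            config.n_instrument + config.n_confounder_snps])
    sig_idx = np.sort(np.concatenate([inst_idx, conf_idx])).astype(int)

    se_exp = rng.uniform(*config.se_exp_range, size=n)
    se_out = rng.uniform(*config.se_out_range, size=n)

    gamma = np.zeros(n)
    beta_exp = se_exp * rng.standard_normal(n)
    if len(sig_idx):
        gamma[sig_idx] = _significant_gammas(rng, se_exp[sig_idx],
                                             config.gamma_sd)
        beta_exp[sig_idx] = _significant_observed(rng, gamma[sig_idx],
                                                  se_exp[sig_idx])

    alpha, is_outlier = _pleiotropy_effects(rng, config, inst_idx, gamma, n)
    beta_out = config.theta * gamma + alpha + se_out * rng.standard_normal(n)

    strand_flipped = rng.random(n) < config.frac_strand_flipped

    base = {
        "rsid": smap["rsid"], "chrom": smap["chrom"], "pos": smap["pos"],
        "eaf": smap["eaf"], "n": float(config.gwas_n),
    }
    exposure = pd.DataFrame({**base,
                             "effect_allele": smap["effect_allele"],
                             "other_allele": smap["other_allele"],
                             "beta": beta_exp, "se": se_exp,
                             "pval": _two_sided_p(beta_exp, se_exp)})
    out_ea = np.where(strand_flipped,
                      smap["effect_allele"].map(_COMPLEMENT),
                      smap["effect_allele"])
    out_oa = np.where(strand_flipped,
                      smap["other_allele"].map(_COMPLEMENT),
                      smap["other_allele"])
    outcome = pd.DataFrame({**base,
                            "effect_allele": out_ea, "other_allele": out_oa,
                            "beta": beta_out, "se": se_out,
                            "pval": _two_sided_p(beta_out, se_out)})

    truth = pd.DataFrame({
        "rsid": smap["rsid"],
        "is_instrument": np.isin(np.arange(n), inst_idx),
        "is_confounder": np.isin(np.arange(n), conf_idx),
        "is_outlier": is_outlier,
        "is_palindromic": smap["is_palindromic"],
        "is_strand_flipped": strand_flipped,
        "gamma": gamma,
        "alpha": alpha,
    })
    from .sumstats import make_table
    exp_table = make_table(exposure, trait_id="exposure",
                           trait_type="continuous")
    out_table = make_table(outcome, trait_id="outcome",
                           trait_type="continuous")
    return exp_table, out_table, truth


def simulate_ld_panel(config: SimulationConfig) -> LdReference:
    """Dosage panel realizing the configured block-LD structure.

    SNPs in a block share a latent factor with loading sqrt(r), giving
    expected pairwise correlation r within the block and ~0 across blocks;
    latent values map affinely into the [0, 2] dosage range. The realized
    r^2 computed from these dosages is what clumping consumes.
    """
    return LdReference.from_panel(panel_frame(config))


def panel_frame(config: SimulationConfig) -> pd.DataFrame:
    """The raw dosage panel as a DataFrame (rows = samples, cols = rsids)."""
    smap = snp_map(config)
    rng = _rng(config, 2)
    n_samples = config.n_panel_samples
    dosages = np.empty((n_samples, len(smap)))
    for block_id, idx in smap.groupby("block").groups.items():
        idx = np.asarray(idx)
        r = float(smap.loc[idx[0], "block_r"])
        latent = rng.standard_normal((n_samples, 1))
        noise = rng.standard_normal((n_samples, len(idx)))
        x = np.sqrt(r) * latent + np.sqrt(1.0 - r) * noise
        dosages[:, idx] = np.clip(1.0 + 0.5 * x, 0.0, 2.0)
    return pd.DataFrame(dosages, columns=smap["rsid"].tolist())


def simulate_confounder_annotations(config: SimulationConfig,
                                    truth: pd.DataFrame) -> pd.DataFrame:
    """PhenoScanner-style annotations matching the truth labels.

    Confounder-labeled SNPs get one of the five screened confounder traits
    at p < 5e-8; a sprinkling of other SNPs is annotated to a neutral trait
    ("height") well above the screening threshold, so non-confounder
    annotations never cause drops.
    """
    rng = _rng(config, 3)
    rows = []
    for _, row in truth.iterrows():
        if row["is_confounder"]:
            trait = DEFAULT_CONFOUNDER_TRAITS[
                rng.integers(len(DEFAULT_CONFOUNDER_TRAITS))]
            pval = 10.0 ** (-rng.uniform(8.5, 20.0))
            rows.append({"rsid": row["rsid"], "trait": trait, "pval": pval})
        elif rng.random() < 0.1:
            pval = 10.0 ** (-rng.uniform(0.0, 5.0))
            rows.append({"rsid": row["rsid"], "trait": "height", "pval": pval})
    return pd.DataFrame(rows, columns=["rsid", "trait", "pval"])


def simulate_study(n_exposures: int = 6, n_outcomes: int = 8,
                   config: SimulationConfig | None = None,
                   effects: dict[tuple[int, int], float] | None = None,
                   reverse_effects: dict[tuple[int, int], float] | None = None,
                   seed: int = 0):
    """A full bi-directional study: shared SNP map, one table per trait.

    Every trait draws its own disjoint instrument set on a shared SNP map
    (so any trait's instruments can be looked up in any other trait's
    table). ``effects[(i, j)]`` sets a true causal effect of exposure i on
    outcome j; ``reverse_effects[(j, i)]`` of outcome j on exposure i. The
    exposure traits are binary (disease-style, log-odds betas), the outcome
    traits continuous.

    Returns ``(exposures, outcomes, ld, annotations)`` ready for
    :class:`~mrlink.pipeline.StudyConfig`.
    """
    config = replace(config or SimulationConfig(), seed=seed)
    n_traits = n_exposures + n_outcomes
    if n_traits * config.n_instrument > config.n_snp:
        raise ConfigurationError(
            "n_snp too small for disjoint per-trait instrument sets")
    effects = effects or {}
    reverse_effects = reverse_effects or {}

    smap = snp_map(config)
    rng = _rng(config, 1)
    n = config.n_snp

    perm = rng.permutation(n)
    inst_sets = [np.sort(perm[t * config.n_instrument:
                              (t + 1) * config.n_instrument])
                 for t in range(n_traits)]
    # remaining SNPs are null everywhere; a slice becomes confounder-flagged
    leftover = np.sort(perm[n_traits * config.n_instrument:])
    conf_idx = leftover[:config.n_confounder_snps]

    se = [rng.uniform(*config.se_exp_range, size=n) for _ in range(n_traits)]
    gamma = np.zeros((n_traits, n))
    for t in range(n_traits):
        idx = inst_sets[t]
        gamma[t, idx] = _significant_gammas(rng, se[t][idx], config.gamma_sd)

    causal = np.zeros((n_traits, n_traits))  # causal[src, dst]
    for (i, j), th in effects.items():
        causal[i, n_exposures + j] = th
    for (j, i), th in reverse_effects.items():
        causal[n_exposures + j, i] = th

    tables = []
    for t in range(n_traits):
        mean = gamma[t].copy()
        for src in range(n_traits):
            if causal[src, t]:
                mean = mean + causal[src, t] * gamma[src]
        beta = mean + se[t] * rng.standard_normal(n)
        idx = inst_sets[t]
        beta[idx] = _significant_observed(rng, mean[idx], se[t][idx])
        flipped = rng.random(n) < config.frac_strand_flipped
        ea = np.where(flipped, smap["effect_allele"].map(_COMPLEMENT),
                      smap["effect_allele"])
        oa = np.where(flipped, smap["other_allele"].map(_COMPLEMENT),
                      smap["other_allele"])
        is_exposure = t < n_exposures
        name = (f"ad_{t + 1}" if is_exposure
                else f"sarcopenia_trait_{t - n_exposures + 1}")
        df = pd.DataFrame({
            "rsid": smap["rsid"], "chrom": smap["chrom"], "pos": smap["pos"],
            "effect_allele": ea, "other_allele": oa, "eaf": smap["eaf"],
            "beta": beta, "se": se[t], "pval": _two_sided_p(beta, se[t]),
            "n": float(config.gwas_n),
        })
        from .sumstats import make_table
        tables.append(make_table(
            df, trait_id=name,
            trait_type="binary" if is_exposure else "continuous"))

    ld = simulate_ld_panel(config)
    truth = pd.DataFrame({
        "rsid": smap["rsid"],
        "is_instrument": False,
        "is_confounder": np.isin(np.arange(n), conf_idx),
        "is_outlier": False,
        "is_palindromic": smap["is_palindromic"],
        "is_strand_flipped": False,
        "gamma": 0.0, "alpha": 0.0,
    })
    annotations = simulate_confounder_annotations(config, truth)
    return tables[:n_exposures], tables[n_exposures:], ld, annotations
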