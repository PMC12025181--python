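"""Synthetic reservoir monitoring data.

Generates abundance and environment tables with the statistical
structure the analysis pipeline assumes: a multi-site, monthly,
multi-year design; a seasonal water-temperature cycle; one
high-nutrient, high-variability "headwater" site; taxa spread over the
seven phyla with functional-group codes consistent with their phylum;
and strictly positive, heavy-right-tailed abundances from
multiplicative lognormal noise.

Mechanisms (deliberately minimal):

* each taxon has a thermal optimum (Gaussian kernel on WT), a
  saturating Monod response to total nitrogen, and a signed affinity
  for the spring mixing/nutrient pulse, so composition turns over
  fastest in April-June;
* each site has a nutrient multiplier, a lognormal noise sigma, and a
  persistent two-state disturbance regime (think alternation between
  mixed and stratified water columns) with per-taxon loadings — the
  headwater site's strong regime swings give its functional groups
  bimodal biomass distributions (high average variation degree) and
  rapid compositional change (high succession rate);
* the lognormal noise is AR(1)-persistent in log space, mimicking
  month-to-month autocorrelation of community states;
* abundances below a detection limit are recorded as 0, so occurrence
  frequencies are informative.

Everything is driven by a single integer seed; the same config and
seed reproduce identical tables. The full generator truth (per-taxon
and per-site parameters) is returned for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AbundanceTable, EnvTable, ENV_VARS, TaxonRecord, ValidationError

#: Functional-group codes a taxon of each phylum may carry.
PHYLUM_FG_CODES = {
    "Chlorophyta": ("F", "G", "J", "N", "T", "X1", "X2", "X3", "P"),
    "Bacillariophyta": ("A", "B", "C", "D", "MP", "P"),
    "Cyanophyta": ("H1", "K", "L_O", "MP", "S1", "S2", "S_N", "TC", "Z"),
    "Dinophyta": ("L_M", "L_O", "Y"),
    "Euglenophyta": ("W1", "W2"),
    "Cryptophyta": ("Y",),
    "Chrysophyta": ("E",),
}

#: log-scale cell-volume (µm³) mean per phylum; diatoms and flagellates large.
_LOG_VOLUME_MEAN = {
    "Chlorophyta": 5.5, "Bacillariophyta": 7.0, "Cyanophyta": 4.5,
    "Dinophyta": 8.0, "Euglenophyta": 7.5, "Cryptophyta": 6.5,
    "Chrysophyta": 6.0,
}

# taxon ecological-response draws: thermal optimum/width (°C) and the
# TN half-saturation's lognormal (log-mean, log-sd) in mg/L
_T_OPT_RANGE = (6.0, 30.0)
_T_WIDTH_RANGE = (10.0, 20.0)
_K_HALF_LOG = (np.log(2.5), 0.4)
_LOADING_MEAN_SD = (1.2, 0.5)
_REGIME_FLIP_PROB = 0.35  # monthly probability the disturbance regime flips
_SPRING_AFFINITY_SD = 0.8  # per-taxon log-response to the spring bloom pulse
_NOISE_AR1 = 0.7  # month-to-month autocorrelation of the log-noise

DEFAULT_PHYLUM_MIX = {
    "Chlorophyta": 0.45, "Bacillariophyta": 0.26, "Cyanophyta": 0.18,
    "Dinophyta": 0.0275, "Euglenophyta": 0.0275, "Cryptophyta": 0.0275,
    "Chrysophyta": 0.0275,
}


@dataclass(frozen=True)
class SiteProfile:
    """Per-site generator knobs.

    nutrient_multiplier scales TN/TP/NH3N/CODMn baselines;
    noise_sigma is the per-observation lognormal sigma;
    disturbance_sigma is the +/- log-amplitude of the two-state
    disturbance regime; pulse is the relative amplitude of the spring
    nutrient pulse in TN/CODMn.
    """

    name: str
    nutrient_multiplier: float = 1.0
    noise_sigma: float = 0.4
    disturbance_sigma: float = 0.05
    pulse: float = 0.2


def default_site_profiles() -> tuple[SiteProfile, ...]:
    """Five sites: one disturbed headwater plus four quieter ones."""
    return (
        SiteProfile("HW1", nutrient_multiplier=2.5, noise_sigma=0.45,
                    disturbance_sigma=1.6, pulse=1.2),
        SiteProfile("S2", noise_sigma=0.4, disturbance_sigma=0.05),
        SiteProfile("S3", noise_sigma=0.4, disturbance_sigma=0.05),
        SiteProfile("S4", noise_sigma=0.4, disturbance_sigma=0.05),
        SiteProfile("S5", noise_sigma=0.4, disturbance_sigma=0.05),
    )


@dataclass
class SimConfig:
    """Study-design parameters for the generator."""

    n_sites: int = 5
    n_months: int = 48
    n_taxa: int = 95
    phylum_mix: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_MIX))
    wt_range: tuple[float, float] = (7.1, 28.3)
    site_profiles: tuple[SiteProfile, ...] = field(
        default_factory=default_site_profiles)
    start_year: int = 2020
    start_month: int = 1
    sample_day: int = 15
    detection_limit: float = 50.0     # cells/L
    env_noise: float = 1.0            # scales environmental noise terms
    seasonal_amplitude: float = 1.0   # scales the WT/nutrient seasonal cycles
    seed: int = 0

    def validate(self) -> None:
        if self.n_months < 2:
            raise ValidationError("n_months must be >= 2")
        if self.n_sites != len(self.site_profiles):
            raise ValidationError("n_sites must match len(site_profiles)")
        if abs(sum(self.phylum_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("phylum_mix must sum to 1")
        if not self.wt_range[0] < self.wt_range[1]:
            raise ValidationError("wt_range must be (min, max) with min < max")
        if self.n_taxa < len(self.phylum_mix):
            raise ValidationError("need at least one taxon per phylum")


def _month_dates(cfg: SimConfig) -> list[_dt.date]:
    dates = []
    y, m = cfg.start_year, cfg.start_month
    for _ in range(cfg.n_months):
        dates.append(_dt.date(y, m, cfg.sample_day))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return dates


def _phylum_counts(cfg: SimConfig) -> dict[str, int]:
    """Integer taxon counts per phylum, largest-remainder rounding."""
    raw = {ph: cfg.n_taxa * frac for ph, frac in cfg.phylum_mix.items()}
    counts = {ph: int(np.floor(v)) for ph, v in raw.items()}
    short = cfg.n_taxa - sum(counts.values())
    for ph in sorted(raw, key=lambda p: raw[p] - counts[p], reverse=True)[:short]:
        counts[ph] += 1
    for ph in counts:
        counts[ph] = max(counts[ph], 1)
    while sum(counts.values()) > cfg.n_taxa:
        big = max(counts, key=counts.get)
        counts[big] -= 1
    return counts


def simulate(config: SimConfig | None = None,
             seed: int | None = None) -> tuple[AbundanceTable, EnvTable, dict]:
    """Generate (abundance, environment, truth) for one synthetic study.

    ``seed`` overrides ``config.seed`` when given. The ``truth`` dict
    records every drawn parameter (per-taxon optima, half-saturations,
    loadings; per-site profiles and disturbance paths) so tests can
    check directional recovery against the configured ground truth.
    """
    cfg = config or SimConfig()
    cfg.validate()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(cfg.seed)
    dates = _month_dates(cfg)
    months = np.array([d.month for d in dates])
    n_t, n_s = cfg.n_months, cfg.n_sites

    # ---- taxa -----------------------------------------------------------
    counts = _phylum_counts(cfg)
    taxa: list[TaxonRecord] = []
    j = 0
    for ph, c in counts.items():
        codes = PHYLUM_FG_CODES[ph]
        for _ in range(c):
            code = codes[int(rng.integers(len(codes)))]
            vol = float(np.exp(rng.normal(_LOG_VOLUME_MEAN[ph], 0.8)))
            taxa.append(TaxonRecord(
                taxon_id=f"t{j:03d}",
                name=f"{ph[:-5]}ella taxon{j:03d} sp.",
                phylum=ph, cell_volume=vol, fg_code=code))
            j += 1
    n_taxa = len(taxa)
    t_opt = rng.uniform(*_T_OPT_RANGE, n_taxa)
    t_width = rng.uniform(*_T_WIDTH_RANGE, n_taxa)
    k_half = np.exp(rng.normal(*_K_HALF_LOG, n_taxa))      # mg/L TN
    base = np.exp(rng.normal(np.log(2.0e4), 1.2, n_taxa))  # cells/L
    loading = rng.normal(*_LOADING_MEAN_SD, n_taxa)        # disturbance loadings
    spring_affinity = rng.normal(0.0, _SPRING_AFFINITY_SD, n_taxa)

    # ---- environment ----------------------------------------------------
    lo, hi = cfg.wt_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0 * cfg.seasonal_amplitude
    season_wt = -np.cos(2 * np.pi * (months - 1) / 12.0)   # min Jan, max Jul
    pulse_shape = np.exp(-((months - 5.0) ** 2) / (2 * 1.5 ** 2))  # Apr-Jun

    env_rows = []
    samples = []
    abundance = np.zeros((n_s * n_t, n_taxa))
    disturbance_paths = {}
    rho = _REGIME_FLIP_PROB
    for si, prof in enumerate(cfg.site_profiles):
        wt = (mid + amp * season_wt
              + cfg.env_noise * rng.normal(0.0, 0.6, n_t))
        seasonal_pulse = 1.0 + prof.pulse * cfg.seasonal_amplitude * pulse_shape
        tn = (1.2 * prof.nutrient_multiplier * seasonal_pulse
              * np.exp(cfg.env_noise * rng.normal(0.0, 0.12, n_t)))
        tp = tn / 25.0 * np.exp(cfg.env_noise * rng.normal(0.0, 0.15, n_t))
        nh3n = (0.06 * prof.nutrient_multiplier
                * np.exp(cfg.env_noise * rng.normal(0.0, 0.3, n_t)))
        codmn = (2.2 * prof.nutrient_multiplier ** 0.8
                 * (1.0 + 0.3 * cfg.seasonal_amplitude * pulse_shape)
                 * np.exp(cfg.env_noise * rng.normal(0.0, 0.1, n_t)))
        do = np.clip(12.5 - 0.28 * (wt - lo)
                     + cfg.env_noise * rng.normal(0.0, 0.7, n_t), 3.0, None)
        ph_col = np.clip(8.1 + cfg.env_noise * rng.normal(0.0, 0.15, n_t),
                         7.2, 8.8)
        sd = np.clip(2.2 / prof.nutrient_multiplier
                     + cfg.env_noise * rng.normal(0.0, 0.3, n_t), 0.3, 4.0)

        # persistent two-state compositional disturbance (e.g. alternation
        # between mixed and stratified states); symmetric +/- log-multipliers
        # with per-taxon loadings, so disturbed sites swing between regimes
        state = 1.0 if rng.random() < 0.5 else -1.0
        d_path = np.empty(n_t)
        flips = rng.random(n_t) < rho
        for t in range(n_t):
            if flips[t]:
                state = -state
            d_path[t] = state * prof.disturbance_sigma
        disturbance_paths[prof.name] = d_path

        thermal = np.exp(-((wt[:, None] - t_opt[None, :]) ** 2)
                         / (2.0 * t_width[None, :] ** 2))
        monod = tn[:, None] / (tn[:, None] + k_half[None, :])
        regime = np.exp(loading[None, :] * d_path[:, None])
        # taxa differ in how strongly they exploit the spring mixing /
        # nutrient pulse, so composition turns over fastest in Apr-Jun
        bloom = np.exp(spring_affinity[None, :] * pulse_shape[:, None]
                       * cfg.seasonal_amplitude)
        # lognormal noise, AR(1)-persistent in log space: month-to-month
        # community states are autocorrelated, but the stationary marginal
        # stays N(0, noise_sigma^2) so stratum-level dispersion is unchanged
        if prof.noise_sigma > 0:
            eps = rng.normal(0.0, 1.0, (n_t, n_taxa))
            z = np.empty_like(eps)
            z[0] = eps[0]
            rn = _NOISE_AR1
            for t in range(1, n_t):
                z[t] = rn * z[t - 1] + np.sqrt(1.0 - rn ** 2) * eps[t]
            noise = np.exp(z * prof.noise_sigma)
        else:
            noise = 1.0
        lam = base[None, :] * thermal * monod * regime * bloom * noise
        lam[lam < cfg.detection_limit] = 0.0
        abundance[si * n_t:(si + 1) * n_t] = lam

        for t, d in enumerate(dates):
            samples.append((prof.name, d))
            env_rows.append((wt[t], ph_col[t], do[t], sd[t], tn[t], tp[t],
                             nh3n[t], codmn[t]))

    table = AbundanceTable(samples=samples, taxa=taxa, abundance=abundance)
    env = EnvTable(samples=list(samples),
                   data=pd.DataFrame(env_rows, columns=list(ENV_VARS)))
    truth = {
        "seed": cfg.seed,
        "config": cfg,
        "site_profiles": {p.name: p for p in cfg.site_profiles},
        "headwater": max(cfg.site_profiles,
                         key=lambda p: p.disturbance_sigma).name,
        "t_opt": t_opt, "t_width": t_width, "k_half": k_half,
        "base": base, "loading": loading, "spring_affinity": spring_affinity,
        "disturbance_paths": disturbance_paths,
    }
    return table, env, truth


def fixture_small() -> tuple[AbundanceTable, EnvTable]:
    """Deterministic 2-site x 4-month x 6-taxon fixture with hand-set values.

    Taxon names match catalog representative species so classification
    can be exercised; fg_code is deliberately left unset. Used in
    documentation and exact-value unit tests.
    """
    taxa = [
        TaxonRecord("t1", "Cyclotella sp.", "Bacillariophyta", 1000.0),
        TaxonRecord("t2", "Synedra sp.", "Bacillariophyta", 500.0),
        TaxonRecord("t3", "Pseudanabaena limnetica", "Cyanophyta", 50.0),
        TaxonRecord("t4", "Cryptomonas sp.", "Cryptophyta", 2000.0),
        TaxonRecord("t5", "Peridinium sp.", "Dinophyta", 8000.0),
        TaxonRecord("t6", "Euglena sp.", "Euglenophyta", 3000.0),
    ]
    dates = [_dt.date(2020, m, 15) for m in (1, 2, 3, 4)]
    samples = [("R1", d) for d in dates] + [("R2", d) for d in dates]
    # cells/L; R1 is the nutrient-rich site with strong compositional
    # swings, R2 rows are exact multiples of one composition (SR = 0)
    abundance = np.array([
        # t1      t2      t3      t4     t5     t6
        [2.0e5, 1.0e5, 8.0e5, 4.0e4, 1.0e4, 2.0e4],
        [4.0e5, 1.0e5, 6.0e5, 6.0e4, 1.0e4, 3.0e4],
        [8.0e5, 2.0e5, 4.0e5, 8.0e4, 2.0e4, 4.0e4],
        [1.6e6, 4.0e5, 2.0e5, 1.2e5, 4.0e4, 8.0e4],
        [1.0e5, 5.0e4, 2.0e5, 2.0e4, 5.0e3, 0.0],
        [1.1e5, 5.5e4, 2.2e5, 2.2e4, 5.5e3, 0.0],
        [1.2e5, 6.0e4, 2.4e5, 2.4e4, 6.0e3, 0.0],
        [1.3e5, 6.5e4, 2.6e5, 2.6e4, 6.5e3, 0.0],
    ])
    env = pd.DataFrame(
        [
            # WT   pH    DO    SD   TN    TP     NH3N  CODMn
            [8.0, 8.0, 11.5, 0.8, 2.50, 0.100, 0.20, 4.5],
            [10.0, 8.1, 11.0, 0.7, 2.80, 0.110, 0.22, 4.8],
            [14.0, 8.2, 10.2, 0.6, 3.10, 0.120, 0.25, 5.1],
            [18.0, 8.3, 9.5, 0.5, 3.40, 0.130, 0.28, 5.4],
            [8.0, 8.0, 11.8, 2.0, 1.20, 0.040, 0.08, 2.2],
            [10.0, 8.1, 11.2, 2.1, 1.25, 0.042, 0.08, 2.3],
            [14.0, 8.2, 10.5, 2.2, 1.30, 0.045, 0.09, 2.4],
            [18.0, 8.3, 9.8, 2.3, 1.35, 0.048, 0.09, 2.5],
        ],
        columns=list(ENV_VARS),
    )
    return (AbundanceTable(samples=samples, taxa=taxa, abundance=abundance),
            EnvTable(samples=list(samples), data=env))
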