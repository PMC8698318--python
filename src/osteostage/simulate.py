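"""Seeded synthetic-data generators with known ground truth.

Every pipeline input can be generated here with the statistical structure
the analysis assumes: piecewise-phase metabolite uptake/secretion rates
with donor and batch effects observed as spent-medium concentration
snapshots; isotopologue intensity vectors convolved with natural 13C
abundance under multiplicative noise; and an expression matrix over a
short differentiation time course with planted switch-like regulons,
decoy regulators and background genes, together with the derived
differential-expression tables and a DoRothEA-like prior.

Each generator returns ``(data, GroundTruth)``; the truth object is meant
for tests and recovery studies only and is never consumed by pipeline
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .isotopes import NATURAL_ABUNDANCE_13C, build_correction_matrix

__all__ = [
    "MetaboliteSimConfig", "IsotopeSimConfig", "ExpressionSimConfig",
    "PlantedRegulon", "GroundTruth", "simulate_metabolite_panel",
    "simulate_isotopologues", "simulate_expression",
    "default_true_distributions", "METABOLITES", "FRESH_MEDIUM_BASELINES",
]

METABOLITES = ["glucose", "lactate", "glutamine", "ammonia", "glutamate"]

#: DMEM/F12-like fresh-medium concentrations, mmol/L (config-exposed)
FRESH_MEDIUM_BASELINES = {
    "glucose": 17.5,
    "glutamine": 2.5,
    "lactate": 0.0,
    "glutamate": 0.05,
    "ammonia": 0.05,
}

# per-metabolite mean hourly rates (mmol/L/h) in the three planted phases;
# secretion positive, uptake negative
_DEFAULT_PHASE_RATES = {
    "glucose": [-0.020, -0.035, -0.015],
    "lactate": [0.040, 0.070, 0.030],
    "glutamine": [-0.008, -0.012, -0.016],
    "ammonia": [0.006, 0.010, 0.014],
    "glutamate": [0.000, 0.002, 0.006],
}


def _default_days() -> list:
    # day 14 is dropped to mimic a day lost to QC and force irregular gaps
    return [d for d in range(1, 29) if d != 14]


@dataclass
class GroundTruth:
    """Planted parameters of a simulation, for tests and recovery studies."""

    change_point_days: list = field(default_factory=list)
    phase_rates: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)
    true_distributions: dict = field(default_factory=dict)
    mean_enrichments: dict = field(default_factory=dict)
    regulons: dict = field(default_factory=dict)
    directions: dict = field(default_factory=dict)
    decoy_regulators: list = field(default_factory=list)

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, set, frozenset)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, indent=1)


@dataclass
class MetaboliteSimConfig:
    """Spent-medium concentration simulator configuration.

    Concentration of a sample taken ``dwell`` hours after a media change is
    ``baseline + (phase rate + donor intercept + batch effect) * dwell +
    noise``, truncated at 0. Rates are piecewise constant over the phases
    delimited by ``phase_boundaries`` (each boundary day is the first day
    of the new phase).
    """

    n_donors: int = 4
    days: list = field(default_factory=_default_days)
    metabolites: list = field(default_factory=lambda: list(METABOLITES))
    phase_boundaries: list = field(default_factory=lambda: [5, 16])
    phase_rates: dict = field(
        default_factory=lambda: {m: list(v)
                                 for m, v in _DEFAULT_PHASE_RATES.items()})
    baselines: dict = field(
        default_factory=lambda: dict(FRESH_MEDIUM_BASELINES))
    donor_sd: float = 0.003   # donor random intercept on the rate, mmol/L/h
    batch_sd: float = 0.002   # analysis-batch offset on the rate, mmol/L/h
    noise_sd: float = 0.04    # residual concentration noise, mmol/L
    media_change_hours: int = 48
    sample_intervals: tuple = (24, 36)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in (self.donor_sd, self.batch_sd, self.noise_sd)):
            raise ValueError("standard deviations must be >= 0")
        bounds = list(self.phase_boundaries)
        if bounds != sorted(set(bounds)):
            raise ValueError("phase_boundaries must be strictly increasing")
        lo, hi = min(self.days), max(self.days)
        if any(not lo < b <= hi for b in bounds):
            raise ValueError(
                f"phase boundaries {bounds} must lie inside days ({lo}, {hi}]"
            )
        for m in self.metabolites:
            if len(self.phase_rates[m]) != len(bounds) + 1:
                raise ValueError(
                    f"{m}: need {len(bounds) + 1} phase rates"
                )

    def phase_of(self, day: int) -> int:
        return int(np.searchsorted(self.phase_boundaries, day, side="right"))

    def dwell_of(self, day: int) -> float:
        order = sorted(self.days).index(day)
        return float(self.sample_intervals[order % len(self.sample_intervals)])


def simulate_metabolite_panel(config: MetaboliteSimConfig):
    """Generate a long spent-medium concentration table plus ground truth."""
    rng = np.random.default_rng(config.seed)
    n_batches = max(1, config.n_donors // 2)
    donor_batch = {f"donor{i + 1}": f"batch{i % n_batches + 1}"
                   for i in range(config.n_donors)}
    donor_eff = {
        (d, m): rng.normal(0.0, config.donor_sd)
        for d in donor_batch for m in config.metabolites
    }
    batch_eff = {
        (b, m): rng.normal(0.0, config.batch_sd)
        for b in sorted(set(donor_batch.values())) for m in config.metabolites
    }
    rows = []
    for donor, batch in donor_batch.items():
        for day in sorted(config.days):
            dwell = config.dwell_of(day)
            phase = config.phase_of(day)
            for m in config.metabolites:
                rate = (config.phase_rates[m][phase]
                        + donor_eff[(donor, m)] + batch_eff[(batch, m)])
                conc = (config.baselines[m] + rate * dwell
                        + rng.normal(0.0, config.noise_sd))
                rows.append({
                    "donor": donor, "day": day, "metabolite": m,
                    "concentration_mmol_per_l": max(0.0, conc),
                    "dwell_hours": dwell, "batch": batch,
                })
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        change_point_days=list(config.phase_boundaries),
        phase_rates={m: list(v) for m, v in config.phase_rates.items()},
        baselines=dict(config.baselines),
    )
    return table, truth


def _mixture(n: int, weights: dict) -> np.ndarray:
    x = np.zeros(n + 1)
    for shift, w in weights.items():
        x[shift] = w
    x[0] += 1.0 - x.sum()
    return x


def default_true_distributions(days=(3, 6, 9, 16, 28)) -> dict:
    """Plausible labeled-fraction trajectories for the traced metabolites.

    Lactate M+3 rises then falls (glycolysis speeding up then slowing);
    UDP-glucose M+6 rises while M+11 falls (glycolysis up, pentose
    phosphate pathway down); glucose is almost fully labeled throughout.
    """
    days = list(days)
    lac_m3 = [0.718, 0.75, 0.81, 0.68, 0.72]
    udp_m6 = [0.20, 0.26, 0.32, 0.40, 0.38]
    udp_m11 = [0.20, 0.16, 0.12, 0.05, 0.06]
    glu_m5 = [0.10, 0.14, 0.18, 0.26, 0.30]
    out = {}
    for i, day in enumerate(days):
        out[("glucose", day)] = _mixture(6, {6: 0.97})
        out[("lactate", day)] = _mixture(3, {3: lac_m3[i % len(lac_m3)]})
        out[("glutamate", day)] = _mixture(
            5, {2: 0.10, 5: glu_m5[i % len(glu_m5)]})
        out[("UDP-glucose", day)] = _mixture(
            11, {6: udp_m6[i % len(udp_m6)], 11: udp_m11[i % len(udp_m11)]})
    return out


@dataclass
class IsotopeSimConfig:
    """Raw isotopologue intensity simulator configuration.

    ``metabolites`` maps name -> carbon count; ``true_distributions`` maps
    ``(metabolite, day)`` -> a length n+1 fraction vector summing to 1.
    The raw vector is the natural-abundance convolution of the truth,
    scaled by a total intensity and protein amount, with multiplicative
    log-normal noise of coefficient of variation ``noise_cv``.
    """

    metabolites: dict = field(default_factory=lambda: {
        "lactate": 3, "glutamate": 5, "glucose": 6, "UDP-glucose": 11})
    days: list = field(default_factory=lambda: [3, 6, 9, 16, 28])
    true_distributions: dict = field(
        default_factory=default_true_distributions)
    natural_abundance: float = NATURAL_ABUNDANCE_13C
    noise_cv: float = 0.02
    total_intensity: float = 1e6
    protein_ug: float = 50.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for (m, day), x in self.true_distributions.items():
            x = np.asarray(x, dtype=float)
            if m not in self.metabolites:
                continue
            if len(x) != self.metabolites[m] + 1:
                raise ValueError(
                    f"{m} day {day}: distribution length {len(x)} != "
                    f"{self.metabolites[m] + 1}"
                )
            if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"{m} day {day}: fractions must be >= 0 and sum to 1"
                )


def simulate_isotopologues(config: IsotopeSimConfig):
    """Generate a long raw-intensity isotopologue table plus ground truth."""
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
    rows = []
    truth = GroundTruth()
    for m, n in config.metabolites.items():
        M = build_correction_matrix(n, config.natural_abundance)
        for day in config.days:
            x = np.asarray(config.true_distributions[(m, day)], dtype=float)
            raw_frac = M @ x
            truth.true_distributions[(m, day)] = x
            truth.mean_enrichments[(m, day)] = float(
                np.dot(np.arange(n + 1), x) / n)
            for rep in range(1, config.n_replicates + 1):
                if sigma > 0:
                    noise = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma,
                                              size=n + 1))
                else:
                    noise = np.ones(n + 1)
                intensities = (config.total_intensity * config.protein_ug
                               / 50.0 * raw_frac * noise)
                for shift, inten in enumerate(intensities):
                    rows.append({
                        "metabolite": m, "day": day, "replicate": rep,
                        "mass_shift": shift, "intensity": inten,
                        "protein_ug": config.protein_ug,
                    })
    return pd.DataFrame(rows), truth


@dataclass
class PlantedRegulon:
    """A regulator with its true target set, direction and amplitude.

    ``switch_day``/``switch_width`` place the regulon's logistic switch in
    time; left as None they fall back to the config-wide defaults.
    Distinct switch timings across regulons are what makes regulons
    separable as expression clusters. ``target_switch_day`` optionally
    delays the targets' switch relative to the regulator's own
    (transcriptional cascade latency); by default targets share the
    regulator's timing.
    """

    regulator: str
    targets: list
    direction: str = "up"
    amplitude: float = 2.0
    switch_day: float | None = None
    switch_width: float | None = None
    target_switch_day: float | None = None


@dataclass
class ExpressionSimConfig:
    """Expression-matrix simulator configuration.

    ``planted_regulons`` may be an explicit list of
    :class:`PlantedRegulon` or an integer count, in which case regulons
    with 8-20 targets are generated (alternating up/down) from the gene
    pool. Regulator profiles follow a monotone logistic switch over the
    time points; targets track their regulator with per-target scaling
    plus Gaussian noise on the log2 scale; background genes are
    stationary noise around their baseline.
    """

    n_genes: int = 1000
    timepoints: list = field(default_factory=lambda: [3, 6, 16, 28])
    n_donors: int = 3
    planted_regulons: object = 10
    decoy_regulators: int = 20
    prior_extra_targets: int = 5
    target_size_range: tuple = (8, 20)
    amplitude: float = 3.0
    noise_sd: float = 0.2
    switch_day: float = 11.0
    switch_width: float = 2.5
    seed: int = 0

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


def _materialize_regulons(config: ExpressionSimConfig, rng) -> list:
    if not isinstance(config.planted_regulons, int):
        regs = list(config.planted_regulons)
        for r in regs:
            if r.amplitude <= 0:
                raise ValueError(f"{r.regulator}: amplitude must be > 0")
            if r.regulator in set(r.targets):
                raise ValueError(
                    f"{r.regulator}: regulator may not be its own target"
                )
        return regs
    lo, hi = config.target_size_range
    sizes = rng.integers(lo, hi + 1, size=config.planted_regulons)
    if sizes.sum() > config.n_genes:
        raise ValueError("more planted target genes than n_genes")
    pool = iter(range(config.n_genes))
    t_lo, t_hi = min(config.timepoints), max(config.timepoints)
    n_per_dir = (config.planted_regulons + 1) // 2
    # stagger switch timings within each direction so regulons form
    # distinct temporal clusters
    switch_days = np.linspace(t_lo + 2.0, t_lo + 0.75 * (t_hi - t_lo),
                              max(n_per_dir, 1))
    regs = []
    for i, size in enumerate(sizes):
        direction = "up" if i % 2 == 0 else "down"
        targets = [f"G{next(pool):04d}" for _ in range(size)]
        regs.append(PlantedRegulon(
            regulator=f"TF{i + 1:02d}", targets=targets,
            direction=direction, amplitude=config.amplitude,
            switch_day=float(switch_days[i // 2]),
            switch_width=config.switch_width,
        ))
    return regs


def simulate_expression(config: ExpressionSimConfig):
    """Generate TPM matrix, DE table, prior database, gene lists and truth.

    Returns ``(tpm, de_table, prior, tf_list, metabolic_genes, truth)``:

    - ``tpm``: genes x samples TPM DataFrame, sample columns labeled
      ``d<day>_<donor>``;
    - ``de_table``: last-vs-first time point DE statistics in the schema
      consumed by :mod:`osteostage.filtering` (t-tests across donors on
      the log2 scale stand in for a count-model fit; only the schema is
      consumed downstream);
    - ``prior``: DataFrame with columns ``regulator, target`` covering
      planted regulators (true + decoy targets) and decoy regulators
      (random target sets);
    - ``tf_list``: planted plus decoy regulator names;
    - ``metabolic_genes``: a deterministic subset of target genes labeled
      as metabolic for annotation tests.
    """
    rng = np.random.default_rng(config.seed)
    regs = _materialize_regulons(config, rng)
    regulator_names = {r.regulator for r in regs}
    # regulators may appear as other regulons' targets (TF-TF cascades),
    # but ordinary target genes must belong to exactly one regulon
    plain_targets = [t for r in regs for t in r.targets
                     if t not in regulator_names]
    if len(set(plain_targets)) != len(plain_targets):
        raise ValueError("planted target sets must be disjoint")
    if len(plain_targets) > config.n_genes:
        raise ValueError("more planted target genes than n_genes")
    planted_targets = plain_targets

    t = np.asarray(config.timepoints, dtype=float)

    def _switch(day, width):
        return 1.0 / (1.0 + np.exp(-(t - day) / width)) - 0.5

    n_cond = config.n_timepoints * config.n_donors
    columns = [f"d{int(day)}_{donor + 1}"
               for day in config.timepoints
               for donor in range(config.n_donors)]
    cond_time = np.repeat(np.arange(config.n_timepoints), config.n_donors)

    background = [f"G{i:04d}" for i in range(config.n_genes)
                  if f"G{i:04d}" not in set(planted_targets)]
    decoys = [f"DTF{i + 1:02d}" for i in range(config.decoy_regulators)]

    profiles = {}
    truth = GroundTruth(decoy_regulators=list(decoys))
    # regulator profiles first: a regulator that is itself another
    # regulon's target keeps its own switch profile
    for r in regs:
        sgn = 1.0 if r.direction == "up" else -1.0
        switch = _switch(r.switch_day or config.switch_day,
                         r.switch_width or config.switch_width)
        base = rng.uniform(4.0, 8.0)
        profiles[r.regulator] = (base + sgn * r.amplitude
                                 * switch[cond_time]
                                 + rng.normal(0.0, config.noise_sd, n_cond))
        truth.regulons[r.regulator] = sorted(r.targets)
        truth.directions[r.regulator] = r.direction
    for r in regs:
        sgn = 1.0 if r.direction == "up" else -1.0
        switch = _switch(r.target_switch_day or r.switch_day
                         or config.switch_day,
                         r.switch_width or config.switch_width)
        for tgt in r.targets:
            if tgt in profiles:
                continue
            scale = rng.uniform(0.8, 1.2)
            tgt_base = rng.uniform(3.0, 8.0)
            profiles[tgt] = (tgt_base + sgn * scale * r.amplitude
                             * switch[cond_time]
                             + rng.normal(0.0, config.noise_sd, n_cond))
    for g in background + decoys:
        base = rng.uniform(3.0, 8.0)
        profiles[g] = base + rng.normal(0.0, config.noise_sd, n_cond)

    log2 = pd.DataFrame(profiles, index=columns).T
    tpm = (2.0 ** log2 - 1.0).clip(lower=0.0)

    de_table = _de_table(log2, tpm, config)

    prior_rows = []
    for r in regs:
        for tgt in r.targets:
            prior_rows.append((r.regulator, tgt))
        n_extra = min(config.prior_extra_targets, len(background))
        if n_extra > 0:
            extra = rng.choice(background, size=n_extra, replace=False)
            for tgt in extra:
                prior_rows.append((r.regulator, str(tgt)))
    # decoy regulators: random target sets mixing response-like and
    # background genes, emulating prior entries whose regulator is itself
    # unresponsive
    lo, hi = config.target_size_range
    for d in decoys:
        size = int(rng.integers(lo, hi + 1))
        n_resp = size // 2 if planted_targets else 0
        chosen = list(rng.choice(planted_targets, size=min(n_resp,
                                                           len(planted_targets)),
                                 replace=False))
        n_bg = min(size - len(chosen), len(background))
        if n_bg > 0:
            chosen += list(rng.choice(background, size=n_bg, replace=False))
        for tgt in chosen:
            prior_rows.append((d, str(tgt)))
    prior = pd.DataFrame(prior_rows, columns=["regulator", "target"])

    tf_list = [r.regulator for r in regs] + decoys
    metabolic_genes = sorted(planted_targets)[::4]
    return tpm, de_table, prior, tf_list, metabolic_genes, truth


def _de_table(log2: pd.DataFrame, tpm: pd.DataFrame,
              config: ExpressionSimConfig) -> pd.DataFrame:
    """Last-vs-first contrast statistics from the simulated replicates."""
    nd = config.n_donors
    first = log2.iloc[:, :nd]
    last = log2.iloc[:, -nd:]
    tpm_first = tpm.iloc[:, :nd]
    tpm_last = tpm.iloc[:, -nd:]
    log2fc = last.mean(axis=1) - first.mean(axis=1)
    with np.errstate(invalid="ignore"):
        _, pvalues = stats.ttest_ind(last, first, axis=1)
    pvalues = np.nan_to_num(pvalues, nan=1.0)
    from statsmodels.stats.multitest import multipletests
    adj = multipletests(pvalues, method="fdr_bh")[1]

    # per-donor calls: normal test against the typical within-condition SD
    pooled_sd = float(np.median(np.concatenate([
        first.std(axis=1, ddof=1).to_numpy(),
        last.std(axis=1, ddof=1).to_numpy(),
    ])))
    pooled_sd = max(pooled_sd, 1e-9)
    table = pd.DataFrame({
        "gene": log2.index,
        "log2fc": log2fc.to_numpy(),
        "pvalue": pvalues,
        "adj_pvalue": adj,
        "mean_tpm_first": tpm_first.mean(axis=1).to_numpy(),
        "mean_tpm_last": tpm_last.mean(axis=1).to_numpy(),
    })

    def _rel_sem(block: pd.DataFrame) -> np.ndarray:
        sem = block.sem(axis=1, ddof=1).to_numpy()
        mean = np.abs(block.mean(axis=1).to_numpy())
        return np.where(mean > 0, sem / np.maximum(mean, 1e-12), 0.0)

    table["rel_sem_first"] = _rel_sem(tpm_first)
    table["rel_sem_last"] = _rel_sem(tpm_last)
    for d in range(nd):
        delta = (last.iloc[:, d] - first.iloc[:, d]).to_numpy()
        z = np.abs(delta) / (pooled_sd * np.sqrt(2.0))
        table[f"log2fc_donor{d + 1}"] = delta
        table[f"sig_donor{d + 1}"] = 2.0 * stats.norm.sf(z) < 0.05
    return table.reset_index(drop=True)
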