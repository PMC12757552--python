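"""Synthetic reporter-intensity and abundance tables with known ground truth.

The redox generator emulates the structure of a sequential-iodoTMT
experiment: per biological sample one SH channel (free thiols) and one Sox
channel (reversibly oxidized thiols), thousands of Cys peptides, log-normal
multiplicative intensity noise at a stated replicate CV, per-channel
multiplicative biases, and zero-intensity missing values. Every generated
quantity is returned as ground truth so downstream estimators can be scored.

Model, per peptide i in sample s of condition c:

    A_i   = 2^Normal(base_mean, base_sd)          peptide base abundance
    Sox   = A_i * ox_ic * eps                      eps ~ mean-1 log-normal,
    SH    = A_i * (1 - ox_ic) * eps'               CV(eps) = replicate_cv
    value = channel_bias * (Sox or SH), zeroed with prob. missing_rate

Base abundance is drawn once per peptide; all sample-to-sample variation is
carried by the noise term, so in the noise-free limit every channel of a
label class has identical medians and median normalization is an exact
fixed point. Channel biases 2^Normal(0, channel_bias_log2_sd) are
mean-centred on the log2 scale within each (plex_run, label_class): only
relative channel offsets are identifiable (an overall class scale is
indistinguishable from base abundance), and with this convention per-class
median normalization removes the planted biases exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ChannelDesign, ParameterError, ReporterTable


class ConfigError(ValueError):
    """A simulation config is infeasible or out of range."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value < 1.0):
        raise ConfigError(f"{name} must be in [0, 1), got {value}")


@dataclass
class SyntheticRedoxConfig:
    """Study conditions for the redox simulator.

    Defaults reproduce the deposited experiments' structure: ~thousands of
    Cys peptides, two conditions with three biological replicates each,
    replicate CV 0.10 (the reported range is 7-12 %), moderate per-channel
    biases, and 5 % zero-intensity missing cells. ``shift_size`` is in
    oxidation percentage points, planted on every condition after the first.
    """

    n_peptides: int = 2000
    conditions: tuple[str, ...] = ("control", "treated")
    n_replicates: int = 3
    true_oxidation: dict[str, np.ndarray] | None = None
    differential_fraction: float = 0.05
    shift_size: float = 15.0
    base_intensity_log2_mean: float = 16.0
    base_intensity_log2_sd: float = 1.5
    replicate_cv: float = 0.10
    channel_bias_log2_sd: float = 0.3
    missing_rate: float = 0.05
    plex_run: str = "plex1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_peptides < 1:
            raise ConfigError("n_peptides must be positive")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")
        if len(self.conditions) < 1:
            raise ConfigError("at least one condition required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition names must be unique")
        _check_prob("differential_fraction", self.differential_fraction)
        _check_prob("missing_rate", self.missing_rate)
        if self.replicate_cv < 0:
            raise ConfigError("replicate_cv must be >= 0")
        if self.channel_bias_log2_sd < 0:
            raise ConfigError("channel_bias_log2_sd must be >= 0")
        if abs(self.shift_size) >= 100:
            raise ConfigError("shift_size must be below 100 percentage points")


@dataclass
class SyntheticTruth:
    """Everything the generator decided: the scoring key for the pipeline."""

    oxidation: pd.DataFrame          # site_key x condition, percent
    channel_bias_log2: pd.Series     # (plex_run, channel_id) -> log2 bias
    differential: pd.Series          # site_key -> bool
    shift: pd.Series                 # site_key -> signed shift actually planted (pp)
    seed: int = 0


# oxidation-fraction bounds: keeps both channels strictly positive so zeros
# only ever come from the missingness process
_OX_LO, _OX_HI = 0.002, 0.995


def _default_oxidation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed resting oxidation: mostly reduced proteome with a small
    highly-oxidized tail (mixture of Beta(1.2, 10) and Beta(8, 2))."""
    base = rng.beta(1.2, 10.0, size=n)
    tail = rng.beta(8.0, 2.0, size=n)
    is_tail = rng.random(n) < 0.03
    return np.clip(np.where(is_tail, tail, base), _OX_LO, _OX_HI)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def make_design(conditions, n_replicates: int, plex_run: str = "plex1") -> ChannelDesign:
    """Paired SH/Sox design: one sample per condition x replicate."""
    rows = []
    for cond in conditions:
        for r in range(1, n_replicates + 1):
            sample = f"{cond}_r{r}"
            for label in ("SH", "Sox"):
                rows.append({
                    "channel_id": f"{sample}_{label}",
                    "plex_run": plex_run,
                    "sample_id": sample,
                    "condition": cond,
                    "replicate": r,
                    "label_class": label,
                })
    return ChannelDesign(pd.DataFrame(rows))


def simulate_redox_experiment(
    config: SyntheticRedoxConfig,
) -> tuple[ReporterTable, ChannelDesign, SyntheticTruth]:
    """Generate a paired SH/Sox reporter table with known truth.

    Deterministic: the same config (including seed) reproduces the output
    bit-exactly. Independent random streams are used for truth, noise,
    biases and missingness, so e.g. switching biases off leaves every other
    draw unchanged.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_noise, rng_bias, rng_missing = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n = config.n_peptides
    conditions = list(config.conditions)
    design = make_design(conditions, config.n_replicates, config.plex_run)

    # --- truth: per-peptide per-condition oxidation fractions -------------
    site_keys = [f"SYN{i:06d}:Cys{(i % 400) + 1}" for i in range(n)]
    accessions = [f"SYN{i:06d}" for i in range(n)]
    positions = [(i % 400) + 1 for i in range(n)]

    if config.true_oxidation is not None:
        ox = {c: np.clip(np.asarray(config.true_oxidation[c], dtype=float),
                         _OX_LO, _OX_HI)
              for c in conditions}
        for c in conditions:
            if ox[c].shape != (n,):
                raise ConfigError(
                    f"true_oxidation[{c!r}] must have length n_peptides"
                )
        differential = pd.Series(False, index=site_keys)
        shift = pd.Series(0.0, index=site_keys)
    else:
        base = _default_oxidation(n, rng_truth)
        n_diff = int(round(config.differential_fraction * n))
        diff_idx = rng_truth.choice(n, size=n_diff, replace=False) if n_diff else \
            np.array([], dtype=int)
        ox = {conditions[0]: base}
        shift_frac = config.shift_size / 100.0
        shifted = base.copy()
        if n_diff:
            shifted[diff_idx] = np.clip(base[diff_idx] + shift_frac, _OX_LO, _OX_HI)
            if np.allclose(shifted[diff_idx], base[diff_idx]):
                raise ConfigError(
                    "shift_size is nullified by the [0,1] oxidation bounds "
                    "for every selected peptide"
                )
        for c in conditions[1:]:
            ox[c] = shifted
        differential = pd.Series(np.isin(np.arange(n), diff_idx), index=site_keys)
        shift = pd.Series(np.where(differential.to_numpy(),
                                   (shifted - base) * 100.0, 0.0),
                          index=site_keys)

    truth_ox = pd.DataFrame({c: ox[c] * 100.0 for c in conditions},
                            index=pd.Index(site_keys, name="site_key"))

    # --- intensities -------------------------------------------------------
    abundance = np.exp2(rng_noise.normal(
        config.base_intensity_log2_mean, config.base_intensity_log2_sd, size=n))

    col_tuples = design.columns
    n_ch = len(col_tuples)
    values = np.empty((n, n_ch))
    for j, (_, ch) in enumerate(col_tuples):
        row = design.frame.iloc[j]
        frac = ox[row["condition"]]
        frac = frac if row["label_class"] == "Sox" else 1.0 - frac
        eps = _lognormal_noise(rng_noise, config.replicate_cv, n)
        values[:, j] = abundance * frac * eps

    # --- channel biases (mean-centred per label class) ---------------------
    bias_log2 = rng_bias.normal(0.0, config.channel_bias_log2_sd, size=n_ch) \
        if config.channel_bias_log2_sd > 0 else np.zeros(n_ch)
    labels = design.frame["label_class"].to_numpy()
    runs = design.frame["plex_run"].to_numpy()
    for run in np.unique(runs):
        for label in ("SH", "Sox"):
            m = (runs == run) & (labels == label)
            if m.any():
                bias_log2[m] -= bias_log2[m].mean()
    values *= np.exp2(bias_log2)[None, :]

    # --- missingness: exact zeros ------------------------------------------
    if config.missing_rate > 0:
        values[rng_missing.random((n, n_ch)) < config.missing_rate] = 0.0

    intens = pd.DataFrame(
        values,
        index=pd.Index(site_keys, name="site_key"),
        columns=pd.MultiIndex.from_tuples(col_tuples,
                                          names=["plex_run", "channel_id"]),
    )
    meta = pd.DataFrame(
        {
            "accession": accessions,
            "sequence": ["SAMPLECPEPTIDE"] * n,
            "cys_positions": [str(p) for p in positions],
            "all_accessions": accessions,
        },
        index=pd.Index(site_keys, name="site_key"),
    )
    table = ReporterTable(intensities=intens, meta=meta)
    truth = SyntheticTruth(
        oxidation=truth_ox,
        channel_bias_log2=pd.Series(bias_log2,
                                    index=pd.MultiIndex.from_tuples(col_tuples)),
        differential=differential,
        shift=shift,
        seed=config.seed,
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# quantitative (abundance) track
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAbundanceConfig:
    """16-plex two-condition protein-abundance simulation."""

    n_proteins: int = 3000
    conditions: tuple[str, str] = ("sensitive", "resistant")
    n_channels: int = 16              # split evenly between the two conditions
    differential_fraction: float = 0.05
    log2_fold_change: float = 1.0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    noise_log2_sd: float = 0.25
    channel_bias_log2_sd: float = 0.2
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if len(self.conditions) != 2:
            raise ConfigError("abundance track compares exactly two conditions")
        if self.n_channels < 4 or self.n_channels % 2:
            raise ConfigError("n_channels must be an even number >= 4")
        _check_prob("differential_fraction", self.differential_fraction)
        _check_prob("missing_rate", self.missing_rate)


@dataclass
class SyntheticAbundanceTruth:
    log2_fold_change: pd.Series      # accession -> planted log2(B/A)
    differential: pd.Series
    channel_bias_log2: pd.Series
    seed: int = 0


def simulate_abundance_experiment(
    config: SyntheticAbundanceConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticAbundanceTruth]:
    """Generate a raw (linear-scale) protein x channel intensity table.

    Returns the raw table (zeros encode missing), a channel-level design
    frame (``channel_id, condition, replicate``) and the planted truth.
    Planted fold-changes carry random sign.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_noise, rng_bias, rng_missing = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n = config.n_proteins
    half = config.n_channels // 2
    cond_a, cond_b = config.conditions
    accessions = [f"PROT{i:05d}" for i in range(n)]

    design_rows = []
    for j in range(config.n_channels):
        cond = cond_a if j < half else cond_b
        design_rows.append({
            "channel_id": f"ch{j + 1:02d}",
            "condition": cond,
            "replicate": (j % half) + 1,
        })
    design = pd.DataFrame(design_rows)

    n_diff = int(round(config.differential_fraction * n))
    diff_idx = rng_truth.choice(n, size=n_diff, replace=False) if n_diff else \
        np.array([], dtype=int)
    signs = rng_truth.choice([-1.0, 1.0], size=n_diff)
    fc = np.zeros(n)
    fc[diff_idx] = signs * config.log2_fold_change

    base = rng_noise.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    log2_vals = np.empty((n, config.n_channels))
    for j in range(config.n_channels):
        cond_shift = fc if j >= half else 0.0
        noise = rng_noise.normal(0.0, config.noise_log2_sd, size=n) \
            if config.noise_log2_sd > 0 else 0.0
        log2_vals[:, j] = base + cond_shift + noise

    bias = rng_bias.normal(0.0, config.channel_bias_log2_sd,
                           size=config.n_channels) \
        if config.channel_bias_log2_sd > 0 else np.zeros(config.n_channels)
    log2_vals += bias[None, :]

    values = np.exp2(log2_vals)
    if config.missing_rate > 0:
        values[rng_missing.random(values.shape) < config.missing_rate] = 0.0

    table = pd.DataFrame(values,
                         index=pd.Index(accessions, name="accession"),
                         columns=design["channel_id"].tolist())
    truth = SyntheticAbundanceTruth(
        log2_fold_change=pd.Series(fc, index=accessions),
        differential=pd.Series(np.isin(np.arange(n), diff_idx), index=accessions),
        channel_bias_log2=pd.Series(bias, index=design["channel_id"].tolist()),
        seed=config.seed,
    )
    return table, design, truth
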