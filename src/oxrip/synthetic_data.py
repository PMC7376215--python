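"""Seeded generators for every pipeline input, with planted ground truth.

The RIP-seq generator emulates the study design the pipeline targets: two
exposure conditions (exposed / control), two fractions per condition
(input / immunoprecipitated), a few biological replicates, NB-distributed
transcript counts with transcript-specific dispersion and per-library size
variation, and planted effects — transcripts enriched in the IP of the
exposed condition only, transcripts enriched in both conditions with a
known exposed-to-control effect ratio, and up/down differential
expression.  The planted truth is returned alongside the counts so every
downstream stage can be scored for recovery.

All generators are pure functions of (config, seed).  A single root seed
is split into independent per-component streams with
``numpy.random.SeedSequence.spawn``, so adding a generator never shifts
the streams of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from oxrip.io_formats import CountMatrix, GeneSetCollection, SampleSheet, make_sample_sheet

_STREAMS = ("truth", "counts", "gmt", "elisa")


@dataclass(frozen=True)
class SimConfig:
    """Simulation design and effect-size distributions.

    Defaults use three replicates per design cell; a two-replicate variant
    (the minimal paired design) is available via ``replicates=2`` and has
    noticeably weaker, characterized-but-not-guaranteed recovery.
    """

    n_transcripts: int = 2000
    replicates: int = 3
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion_range: tuple[float, float] = (0.01, 0.3)
    library_factor_range: tuple[float, float] = (0.5, 2.0)
    n_enriched_exposed_only: int = 100
    enrichment_log2_range: tuple[float, float] = (3.0, 8.0)
    n_enriched_both: int = 50
    both_ratio_range: tuple[float, float] = (1.0, 3.0)
    n_de_up: int = 50
    n_de_down: int = 50
    de_log2_range: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        n_planted = (
            self.n_enriched_exposed_only + self.n_enriched_both + self.n_de_up + self.n_de_down
        )
        if n_planted > self.n_transcripts:
            raise ValueError(
                f"planted sets ({n_planted}) exceed n_transcripts ({self.n_transcripts})"
            )
        for name, rng in (
            ("dispersion_range", self.dispersion_range),
            ("library_factor_range", self.library_factor_range),
        ):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"invalid {name}: {rng}")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per design cell")


@dataclass(frozen=True)
class SimTruth:
    """Planted per-transcript parameters and per-sample library factors."""

    params: pd.DataFrame  # baseline_mean, dispersion, enrich_exposed, enrich_control, de_effect
    library_factors: pd.Series
    seed: int
    ratio_threshold: float = 1.5
    config: SimConfig = field(default_factory=SimConfig)

    @property
    def enriched_exposed_only(self) -> frozenset[str]:
        p = self.params
        return frozenset(p.index[(p["enrich_exposed"] > 0) & (p["enrich_control"] == 0)])

    @property
    def enriched_both(self) -> frozenset[str]:
        p = self.params
        return frozenset(p.index[(p["enrich_exposed"] > 0) & (p["enrich_control"] > 0)])

    @property
    def de_up(self) -> frozenset[str]:
        return frozenset(self.params.index[self.params["de_effect"] > 0])

    @property
    def de_down(self) -> frozenset[str]:
        return frozenset(self.params.index[self.params["de_effect"] < 0])

    def planted_induced(self, ratio_threshold: float | None = None) -> frozenset[str]:
        """Ground-truth induced set: exposed-only transcripts plus both-condition
        transcripts whose true enrichment ratio exceeds the threshold."""
        thr = self.ratio_threshold if ratio_threshold is None else ratio_threshold
        p = self.params
        both = p.index[
            (p["enrich_control"] > 0)
            & (2.0 ** (p["enrich_exposed"] - p["enrich_control"]) > thr)
        ]
        return self.enriched_exposed_only | frozenset(both)


def _rng_for(seed: int, component: str) -> np.random.Generator:
    idx = _STREAMS.index(component)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STREAMS))[idx])


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with Var = mu + alpha*mu^2 (Poisson limit at alpha ~ 0)."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_like = alpha < 1e-12
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mean[poisson_like])
    nb = ~poisson_like
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_ripseq(
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Generate a counts matrix, sample sheet and ground truth for one run."""
    truth_rng = _rng_for(seed, "truth")
    count_rng = _rng_for(seed, "counts")
    n = config.n_transcripts
    ids = [f"TX{i:05d}" for i in range(n)]

    baseline = 2.0 ** truth_rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    lo, hi = config.dispersion_range
    dispersion = np.exp(truth_rng.uniform(np.log(lo), np.log(hi), n))

    order = truth_rng.permutation(n)
    sizes = [config.n_enriched_exposed_only, config.n_enriched_both, config.n_de_up, config.n_de_down]
    cut = np.cumsum([0, *sizes])
    idx_exp_only, idx_both, idx_up, idx_down = (
        order[cut[i]:cut[i + 1]] for i in range(4)
    )

    enrich_exposed = np.zeros(n)
    enrich_control = np.zeros(n)
    e_lo, e_hi = config.enrichment_log2_range
    enrich_exposed[idx_exp_only] = truth_rng.uniform(e_lo, e_hi, len(idx_exp_only))
    base_ctl = truth_rng.uniform(e_lo, e_hi, len(idx_both))
    r_lo, r_hi = config.both_ratio_range
    ratios = truth_rng.uniform(r_lo, r_hi, len(idx_both))
    enrich_control[idx_both] = base_ctl
    enrich_exposed[idx_both] = base_ctl + np.log2(ratios)

    de_effect = np.zeros(n)
    d_lo, d_hi = config.de_log2_range
    de_effect[idx_up] = truth_rng.uniform(d_lo, d_hi, len(idx_up))
    de_effect[idx_down] = -truth_rng.uniform(d_lo, d_hi, len(idx_down))

    rows = []
    for condition in ("exposed", "control"):
        for fraction in ("input", "rip"):
            for rep in range(1, config.replicates + 1):
                rows.append((f"{condition}_{fraction}_{rep}", condition, fraction, rep))
    sheet = make_sample_sheet(rows)
    f_lo, f_hi = config.library_factor_range
    lib = np.exp(truth_rng.uniform(np.log(f_lo), np.log(f_hi), len(rows)))
    lib_series = pd.Series(lib, index=sheet.sample_ids, name="library_factor")

    counts = np.empty((n, len(rows)), dtype=np.int64)
    for j, (_sid, condition, fraction, _rep) in enumerate(rows):
        log2_effect = de_effect * (condition == "exposed")
        if fraction == "rip":
            log2_effect = log2_effect + (
                enrich_exposed if condition == "exposed" else enrich_control
            )
        mean_j = lib[j] * baseline * 2.0**log2_effect
        counts[:, j] = _draw_nb(count_rng, mean_j, dispersion)

    matrix = CountMatrix(pd.DataFrame(counts, index=ids, columns=sheet.sample_ids), sheet)
    params = pd.DataFrame(
        {
            "baseline_mean": baseline,
            "dispersion": dispersion,
            "enrich_exposed": enrich_exposed,
            "enrich_control": enrich_control,
            "de_effect": de_effect,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    truth = SimTruth(params, lib_series, seed=seed, config=config)
    return matrix, sheet, truth


def simulate_gmt(
    truth: SimTruth,
    n_sets: int = 20,
    seed: int = 0,
    *,
    set_size_range: tuple[int, int] = (20, 80),
    spike_size: int = 30,
    spike_purity: float = 0.9,
) -> GeneSetCollection:
    """Random gene sets plus one set spiked with planted enriched transcripts.

    The spiked set draws ``spike_purity`` of its members from the planted
    enriched transcripts (exposed-only plus both-condition) and the rest at
    random, giving the over-representation test a known positive.
    """
    rng = _rng_for(seed, "gmt")
    universe = np.asarray(truth.params.index)
    enriched = sorted(truth.enriched_exposed_only | truth.enriched_both)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = ("random background set", frozenset(members))
    n_spike = min(spike_size, len(enriched))
    n_from_enriched = int(round(spike_purity * n_spike))
    spike = list(rng.choice(np.asarray(enriched), size=n_from_enriched, replace=False))
    others = np.asarray(sorted(set(universe) - set(enriched)))
    spike += list(rng.choice(others, size=n_spike - n_from_enriched, replace=False))
    sets["SPIKED_OXIDIZED_SET"] = ("set spiked with planted enriched transcripts", frozenset(spike))
    return GeneSetCollection(sets)


def simulate_elisa(
    a: float = 3.12,
    b: float = -0.72,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    true_conc: float = 150.0,
    dilution_factors: tuple[float, ...] = (1.0, 2.0),
    standard_concs: tuple[float, ...] = (10.3, 30.0, 90.0, 270.0, 810.0, 3000.0),
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Simulate competitive-ELISA standard and sample readings.

    Readings follow ``logit(B/B0) = a + b*ln(conc) + eps`` with Gaussian
    noise on the logit scale (sd `noise_sd`); samples are read at the given
    dilutions of a known `true_conc` (pg/ml).  Returns (standards, samples,
    truth) where standards has columns conc/replicate/b_over_b0, samples
    has dilution_factor/replicate/b_over_b0, and truth records the planted
    curve and concentration.
    """
    if b >= 0:
        raise ValueError("competitive curve slope b must be negative")
    rng = _rng_for(seed, "elisa")
    std_rows = []
    for conc in standard_concs:
        for rep in range(1, n_replicates + 1):
            eta = a + b * np.log(conc) + rng.normal(0.0, noise_sd)
            std_rows.append((conc, rep, float(expit(eta))))
    standards = pd.DataFrame(std_rows, columns=["conc", "replicate", "b_over_b0"])
    sample_rows = []
    for dilution in dilution_factors:
        well_conc = true_conc / dilution
        for rep in range(1, n_replicates + 1):
            eta = a + b * np.log(well_conc) + rng.normal(0.0, noise_sd)
            sample_rows.append((dilution, rep, float(expit(eta))))
    samples = pd.DataFrame(sample_rows, columns=["dilution_factor", "replicate", "b_over_b0"])
    return standards, samples, {"a": a, "b": b, "true_conc": true_conc}
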