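"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) F2 seed-class counts under a true recombinant fraction,
(b) biallelic Col/Ler marker maps, (c) recombinant breakpoints drawn from
a hotspot-intensity mixture, and (d) per-marker allele depths observed
through finite sequencing depth with symmetric per-base error. Every
generator is a pure function of its parameters and RNG seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seed_rf import SeedCount, expected_seed_class_probs
from .xo_mapper import (
    AlleleDepthTable,
    Marker,
    MarkerSupport,
    Orientation,
    SnpMap,
)

__all__ = [
    "MixtureComponent",
    "HotspotMixtureModel",
    "RecombinantTruth",
    "SimTruth",
    "simulate_seed_counts",
    "make_snp_map",
    "simulate_recombinants",
    "simulate_allele_depths",
    "simulate_marker_support",
    "suppress_hotspot",
    "chp_like_model",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MixtureComponent:
    """One hotspot: a span with its crossover-probability weight."""

    name: str
    start: int  # 1-based half-open [start, end)
    end: int
    weight: float


@dataclass(frozen=True)
class HotspotMixtureModel:
    """Breakpoint-intensity mixture: hotspots plus interval-wide background.

    A breakpoint picks a hotspot (or the background, whose span is the
    whole interval) with probability equal to its weight, then falls
    uniformly within the chosen span.
    """

    interval_start: int
    interval_end: int
    components: tuple[MixtureComponent, ...]
    background_weight: float

    def __post_init__(self) -> None:
        w = [c.weight for c in self.components] + [self.background_weight]
        if any(x < 0 for x in w):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mixture weights plus background must sum to 1")
        for c in self.components:
            if not self.interval_start <= c.start < c.end <= self.interval_end + 1:
                raise ValueError(f"component {c.name} outside the interval")

    @property
    def length(self) -> int:
        return self.interval_end - self.interval_start + 1

    def span_probability(self, start: int, end: int) -> float:
        """Probability that a breakpoint lands in [start, end)."""
        p = self.background_weight * max(0, min(end, self.interval_end + 1) - max(start, self.interval_start)) / self.length
        for c in self.components:
            overlap = max(0, min(end, c.end) - max(start, c.start))
            p += c.weight * overlap / (c.end - c.start)
        return p


@dataclass(frozen=True)
class RecombinantTruth:
    """True breakpoint position(s) and orientation for one recombinant."""

    recombinant_id: str
    breakpoints: tuple[int, ...]
    orientation: Orientation


@dataclass
class SimTruth:
    """Ground-truth sidecar for one simulated dataset."""

    rng_seed: int
    params: dict = field(default_factory=dict)
    r_true: float | None = None
    recombinants: list[RecombinantTruth] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = dict(
            rng_seed=self.rng_seed,
            params=self.params,
            r_true=self.r_true,
            recombinants=[
                dict(
                    recombinant_id=t.recombinant_id,
                    breakpoints=list(t.breakpoints),
                    orientation=t.orientation.value,
                )
                for t in self.recombinants
            ],
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_seed_counts(
    r_true: float,
    n_total: int,
    rng_seed: int,
    cross_id: str = "sim",
) -> tuple[SeedCount, SimTruth]:
    """Draw (NG, NR, other) multinomially from the gamete model at r_true."""
    probs = expected_seed_class_probs(r_true)
    rng = np.random.default_rng(rng_seed)
    ng, nr, _ = rng.multinomial(
        n_total, [probs.p_green_only, probs.p_red_only, probs.p_other]
    )
    counts = SeedCount(cross_id=cross_id, n_green=int(ng), n_red=int(nr), n_total=n_total)
    truth = SimTruth(rng_seed=rng_seed, r_true=r_true, params=dict(n_total=n_total))
    return counts, truth


def make_snp_map(
    interval_length: int,
    n_markers: int,
    rng_seed: int = 0,
    spacing: str = "uniform",
    interval_name: str = "sim_interval",
    chrom: str = "chrSim",
) -> SnpMap:
    """Marker map over [1, interval_length] with uniform or random spacing.

    Uniform mode places markers at the declared extremes and evenly in
    between; random mode samples positions without replacement. Alleles
    are random distinct bases in both modes (seeded).
    """
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    if n_markers > interval_length:
        raise ValueError("more markers than base pairs in the interval")
    rng = np.random.default_rng(rng_seed)
    if spacing == "uniform":
        positions = np.unique(np.round(np.linspace(1, interval_length, n_markers)).astype(np.int64))
    elif spacing == "random":
        positions = np.sort(
            rng.choice(np.arange(1, interval_length + 1), size=n_markers, replace=False)
        )
    else:
        raise ValueError("spacing must be 'uniform' or 'random'")
    col_idx = rng.integers(0, 4, size=positions.size)
    ler_idx = (col_idx + rng.integers(1, 4, size=positions.size)) % 4
    markers = tuple(
        Marker(int(p), _BASES[ci], _BASES[li], f"m{k + 1:04d}")
        for k, (p, ci, li) in enumerate(zip(positions, col_idx, ler_idx))
    )
    return SnpMap(interval_name, chrom, 1, interval_length, markers)


def simulate_recombinants(
    n: int,
    model: HotspotMixtureModel,
    rng_seed: int,
    double_co_fraction: float = 0.0,
    id_prefix: str = "rec",
) -> SimTruth:
    """Draw breakpoints from the hotspot mixture; orientation is fair coin.

    A ``double_co_fraction`` of recombinants receive a second breakpoint
    (drawn independently from the same mixture) to emulate rare
    double-crossover chromatids, which the caller should reject.
    """
    if not 0.0 <= double_co_fraction <= 1.0:
        raise ValueError("double_co_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    spans = [(c.start, c.end) for c in model.components]
    spans.append((model.interval_start, model.interval_end + 1))
    weights = [c.weight for c in model.components] + [model.background_weight]

    def draw_breakpoint() -> int:
        k = rng.choice(len(spans), p=weights)
        lo, hi = spans[k]
        return int(rng.integers(lo, hi))

    recs = []
    for i in range(n):
        bps = [draw_breakpoint()]
        if rng.random() < double_co_fraction:
            second = draw_breakpoint()
            while second == bps[0]:
                second = draw_breakpoint()
            bps.append(second)
        ori = Orientation.LER_TO_HET if rng.random() < 0.5 else Orientation.HET_TO_LER
        recs.append(RecombinantTruth(f"{id_prefix}{i + 1:05d}", tuple(sorted(bps)), ori))
    return SimTruth(
        rng_seed=rng_seed,
        params=dict(n=n, double_co_fraction=double_co_fraction),
        recombinants=recs,
    )


def _expected_col_fraction(truth: RecombinantTruth, positions: np.ndarray) -> np.ndarray:
    """True Col-read fraction per marker: 0 on Ler blocks, 0.5 on het blocks."""
    # number of breakpoints left of each marker flips the block parity
    flips = np.searchsorted(np.asarray(truth.breakpoints), positions, side="left")
    first_het = truth.orientation is Orientation.HET_TO_LER
    het = (flips % 2 == 0) if first_het else (flips % 2 == 1)
    return np.where(het, 0.5, 0.0)


def simulate_allele_depths(
    truth: SimTruth,
    snps: SnpMap,
    mean_depth: float,
    error_rate: float,
    rng_seed: int,
) -> list[AlleleDepthTable]:
    """Observe each recombinant's haplotype through noisy finite depth.

    Per marker the total depth is Poisson(mean_depth) and Col-supporting
    reads are Binomial(depth, p(1-e) + (1-p)e) where p is the true Col
    fraction (0 or 0.5) and e the symmetric allele-flip error rate.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(rng_seed)
    positions = snps.positions
    n_rec, n_mark = len(truth.recombinants), positions.size
    p_true = np.vstack(
        [_expected_col_fraction(t, positions) for t in truth.recombinants]
    ) if n_rec else np.zeros((0, n_mark))
    p_obs = p_true * (1.0 - error_rate) + (1.0 - p_true) * error_rate
    depth = rng.poisson(mean_depth, size=(n_rec, n_mark))
    col = rng.binomial(depth, p_obs)
    ids = list(snps.marker_ids)
    return [
        AlleleDepthTable(t.recombinant_id, ids, col[i], depth[i] - col[i])
        for i, t in enumerate(truth.recombinants)
    ]


def simulate_marker_support(
    snps: SnpMap,
    bad_fraction: float,
    n_obs: int,
    rng_seed: int,
    bad_support: float = 0.5,
    good_support: float = 0.995,
) -> tuple[list[MarkerSupport], set[str]]:
    """Candidate-marker support panel with a labelled bad subset.

    Good sites show the declared parental allele in ``good_support`` of
    control observations in expectation; bad sites in ``bad_support``.
    Returns the candidates plus the set of bad marker ids.
    """
    rng = np.random.default_rng(rng_seed)
    bad = set(
        rng.choice(
            snps.marker_ids,
            size=int(round(bad_fraction * len(snps))),
            replace=False,
        ).tolist()
    )
    candidates = []
    for m in snps.markers:
        p = bad_support if m.id in bad else good_support
        candidates.append(
            MarkerSupport(
                position=m.position,
                col_allele=m.col_allele,
                ler_allele=m.ler_allele,
                id=m.id,
                n_obs=n_obs,
                n_concordant=int(rng.binomial(n_obs, p)),
            )
        )
    return candidates, bad


def suppress_hotspot(
    model: HotspotMixtureModel, name: str, reduction_pct: float
) -> HotspotMixtureModel:
    """Model whose normalized share at one hotspot is reduced by a known %.

    The returned mixture satisfies
    ``span_probability(hotspot) = (1 - reduction_pct/100) * original`` with
    all weights still summing to 1: the target component's weight is
    scaled down and every other weight (including background) is scaled
    up to absorb the released mass — crossovers suppressed at the hotspot
    reappear elsewhere, as normalized landscapes require. Solves::

        alpha * w_c + beta * (1 - w_c)        = 1
        alpha * w_c + beta * w_bg * f_c       = (1 - rho) * s_c

    where s_c is the original span probability and f_c the span's share
    of the interval length.
    """
    comp = {c.name: c for c in model.components}
    if name not in comp:
        raise ValueError(f"no component named {name!r}")
    target = comp[name]
    rho = reduction_pct / 100.0
    f_c = (target.end - target.start) / model.length
    s_c = model.span_probability(target.start, target.end)
    w_c = target.weight
    denom = 1.0 - w_c - model.background_weight * f_c  # = 1 - s_c
    beta = (1.0 - (1.0 - rho) * s_c) / denom
    alpha = (1.0 - beta * (1.0 - w_c)) / w_c
    if alpha < 0:
        raise ValueError("requested reduction is infeasible for this mixture")
    new_components = tuple(
        MixtureComponent(c.name, c.start, c.end, c.weight * (alpha if c.name == name else beta))
        for c in model.components
    )
    return HotspotMixtureModel(
        interval_start=model.interval_start,
        interval_end=model.interval_end,
        components=new_components,
        background_weight=model.background_weight * beta,
    )


def chp_like_model(snps: SnpMap | None = None) -> HotspotMixtureModel:
    """Default study conditions: a 40-kb interval with three hotspots.

    Mirrors the empirical structure of a short pericentromeric interval
    with three distinct hotspots, the central one strongest: weights
    0.20 / 0.45 / 0.25 with 0.10 interval-wide background. When a marker
    map is supplied, hotspot edges are snapped to marker positions so
    that a span contains a crossover's inter-marker midpoint exactly when
    it contains the true breakpoint (membership is decided at marker
    resolution either way).
    """
    if snps is None:
        snps = make_snp_map(40_000, 101, rng_seed=0)
    pos = snps.positions

    def span(frac_lo: float, frac_hi: float) -> tuple[int, int]:
        lo = int(pos[int(round(frac_lo * (pos.size - 1)))])
        hi = int(pos[int(round(frac_hi * (pos.size - 1)))])
        return lo, hi

    a = span(0.12, 0.18)
    c = span(0.42, 0.55)
    n = span(0.74, 0.80)
    return HotspotMixtureModel(
        interval_start=snps.start,
        interval_end=snps.end,
        components=(
            MixtureComponent("Aro", a[0], a[1], 0.20),
            MixtureComponent("Coco", c[0], c[1], 0.45),
            MixtureComponent("Nala", n[0], n[1], 0.25),
        ),
        background_weight=0.10,
    )
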