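"""Bootstrap determination of the minimum IPI sample size per song.

For the songs with the most IPIs (top 5% of the dataset by count), subsample
n IPIs per iteration for n in {3, 5, 10, 15, 20, 25, 30} over 10,000
iterations, and summarize the distribution of subsample means (mean, SD,
percentile confidence interval) per sample size. A quantitative stabilization
rule replaces the study's visual read-out: the smallest n at which, for every
selected song, the SD of subsample means has stopped shrinking appreciably
and the CI is narrow relative to the full-song mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from coldsong.song import IPISeries

DEFAULT_SAMPLE_SIZES = (3, 5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class BootstrapSpec:
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    n_iterations: int = 10_000
    top_fraction: float = 0.05
    ci_level: float = 0.95
    with_replacement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(sorted(self.sample_sizes)) != tuple(self.sample_sizes):
            raise ValueError("sample_sizes must be sorted ascending")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SizeSummary:
    """Distribution of subsample means at one sample size."""

    sample_size: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BootstrapResult:
    song_id: str
    full_song_mean: float
    n_ipi_total: int
    per_size: dict[int, SizeSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "song_id": self.song_id,
            "sample_size": s.sample_size,
            "mean_of_means": s.mean,
            "sd_of_means": s.sd,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "full_song_mean": self.full_song_mean,
            "n_ipi_total": self.n_ipi_total,
        } for s in self.per_size.values()])


def select_top_songs(songs: list[IPISeries],
                     top_fraction: float = 0.05) -> list[IPISeries]:
    """The ceil(top_fraction x N) songs with the largest IPI counts.

    Ties are broken by song_id order (lexicographic), so selection is
    deterministic.
    """
    if not songs:
        raise ValueError("song list is empty")
    k = int(np.ceil(top_fraction * len(songs)))
    ranked = sorted(songs, key=lambda s: (-s.n_ipi, s.song_id))
    return ranked[:k]


def bootstrap_song(ipis: IPISeries, spec: BootstrapSpec) -> BootstrapResult:
    """Subsample-mean distributions for one song at each sample size.

    With replacement (the default) any song with >= 1 IPI is usable; without
    replacement the song must have at least max(sample_sizes) IPIs.
    """
    values = ipis.ipis_ms
    if not spec.with_replacement and values.size < max(spec.sample_sizes):
        raise ValueError(
            f"song {ipis.song_id!r} has {values.size} IPIs, fewer than the "
            f"largest sample size {max(spec.sample_sizes)} required for "
            "sampling without replacement")
    if values.size == 0:
        raise ValueError(f"song {ipis.song_id!r} has no IPIs")
    rng = np.random.default_rng(spec.seed)
    alpha = (1 - spec.ci_level) / 2
    per_size = {}
    for n in spec.sample_sizes:
        if spec.with_replacement:
            draws = rng.choice(values, size=(spec.n_iterations, n), replace=True)
        else:
            # vectorized without-replacement: first n of a random permutation
            order = np.argsort(rng.random((spec.n_iterations, values.size)),
                               axis=1)[:, :n]
            draws = values[order]
        means = draws.mean(axis=1)
        per_size[n] = SizeSummary(
            sample_size=n,
            mean=float(means.mean()),
            sd=float(means.std(ddof=1)) if spec.n_iterations > 1 else 0.0,
            ci_low=float(np.quantile(means, alpha)),
            ci_high=float(np.quantile(means, 1 - alpha)),
        )
    return BootstrapResult(ipis.song_id, float(values.mean()),
                           int(values.size), per_size)


def bootstrap_songs(songs: list[IPISeries],
                    spec: BootstrapSpec) -> list[BootstrapResult]:
    """Bootstrap each selected song; per-song seeds derived from spec.seed."""
    seq = np.random.SeedSequence(spec.seed)
    results = []
    for ipis, child in zip(songs, seq.spawn(len(songs))):
        song_spec = BootstrapSpec(
            sample_sizes=spec.sample_sizes, n_iterations=spec.n_iterations,
            top_fraction=spec.top_fraction, ci_level=spec.ci_level,
            with_replacement=spec.with_replacement,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        results.append(bootstrap_song(ipis, song_spec))
    return results


def stabilization_size(results: list[BootstrapResult],
                       sd_decrease_threshold: float = 0.20,
                       ci_halfwidth_fraction: float = 0.05) -> int:
    """Smallest sample size at which subsample-mean variation has stabilized.

    A sample size qualifies when, for every song, (a) the relative decrease
    in SD of subsample means versus the previous sample size is below
    ``sd_decrease_threshold`` (the smallest size counts as zero decrease),
    and (b) the CI half-width is below ``ci_halfwidth_fraction`` of the
    full-song mean. If no size qualifies, the largest tested size is
    returned with a warning.
    """
    if not results:
        raise ValueError("no bootstrap results")
    sizes = sorted(results[0].per_size)
    if len(sizes) < 2:
        raise ValueError("need >= 2 sample sizes")
    for i, n in enumerate(sizes):
        ok = True
        for res in results:
            cur = res.per_size[n]
            if i > 0:
                prev = res.per_size[sizes[i - 1]]
                decrease = 0.0 if prev.sd == 0 else (prev.sd - cur.sd) / prev.sd
                if decrease >= sd_decrease_threshold:
                    ok = False
                    break
            halfwidth = (cur.ci_high - cur.ci_low) / 2
            if halfwidth >= ci_halfwidth_fraction * abs(res.full_song_mean):
                ok = False
                break
        if ok:
            return n
    warnings.warn("stabilization criterion never met; returning the largest "
                  f"tested sample size {sizes[-1]}", stacklevel=2)
    return sizes[-1]


def results_long_table(results: list[BootstrapResult]) -> pd.DataFrame:
    """Plot-ready long-format table, one row per song x sample size."""
    if not results:
        return pd.DataFrame(columns=["song_id", "sample_size", "mean_of_means",
                                     "sd_of_means", "ci_low", "ci_high",
                                     "full_song_mean", "n_ipi_total"])
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
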