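"""H3K9me2 signal processing and broad-domain calling.

The pipeline mirrors standard broad-mark ChIP processing: depth-normalised
coverage is smoothed by re-binning 5 kb bins over a centre-anchored 10 kb
window (zero-signal locations are treated as uninformative and ignored),
ChIP is normalised to input as log2(ChIP/Input) per bin, and domains are
called by percentile seeding — bins above the genome-wide 80th percentile
seed a domain, which extends up- and downstream until signal drops below the
30th percentile.  A two-component Gaussian mixture fitted to the genome-wide
log-ratio distribution decomposes it into "noise" and "signal" components;
the signal component's mixing weight (lambda2) estimates the fraction of the
genome carrying the mark and anchors inter-sample scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .genome_model import BinnedTrack, GenomicInterval


class DegenerateMixtureWarning(UserWarning):
    """The two components are not meaningfully separated."""


@dataclass
class RatioTrack:
    """log2(ChIP/Input) bins with provenance."""

    track: BinnedTrack
    sample_id: str = ""
    scale_factor: float = 1.0


@dataclass
class K9Domain:
    """A contiguous high-signal region with seed/boundary provenance."""

    interval: GenomicInterval
    seed_bins: int
    mean_ratio: float


@dataclass
class MixtureFit:
    """Two-component Gaussian decomposition of a log-ratio distribution.

    Component 2 is the higher-mean ("signal") component by convention;
    ``lambda2`` is its mixing weight.
    """

    lambdas: tuple[float, float]
    means: tuple[float, float]
    sigmas: tuple[float, float]
    log_likelihood: float
    converged: bool
    n_bins: int

    @property
    def lambda2(self) -> float:
        return self.lambdas[1]


def rebin_sliding(track: BinnedTrack, window: int) -> BinnedTrack:
    """Smooth a binned track with a centre-anchored window mean.

    Each output bin (same width as the input) holds the overlap-weighted mean
    of the non-zero, non-missing source values within the ``window`` centred
    on that bin.  Zero bins are treated as uninformative (unmappable or
    masked regions) and contribute nothing; a window with no informative
    signal yields a missing bin.
    """
    w = track.bin_width
    if window < w:
        raise ValueError("window must be >= bin width")
    if window % w != 0:
        raise ValueError("window must be a multiple of bin width")

    half = (window - w) / 2  # overhang on each side, in bp
    full = int(half // w)    # fully covered flank bins
    frac = (half - full * w) / w  # fractional coverage of the outermost bin

    out: dict[str, np.ndarray] = {}
    for chrom, vals in track.values.items():
        informative = np.isfinite(vals) & (vals != 0)
        v = np.where(informative, vals, 0.0)
        wts = informative.astype(float)

        num = v.copy()
        den = wts.copy()
        for k in range(1, full + 1):
            num[:-k] += v[k:]
            den[:-k] += wts[k:]
            num[k:] += v[:-k]
            den[k:] += wts[:-k]
        if frac > 0:
            k = full + 1
            num[:-k] += frac * v[k:]
            den[:-k] += frac * wts[k:]
            num[k:] += frac * v[:-k]
            den[k:] += frac * wts[:-k]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = num / den
        res[den == 0] = np.nan
        out[chrom] = res
    return BinnedTrack(w, out, dict(track.chrom_lengths))


def log2_ratio(chip: BinnedTrack, input_: BinnedTrack,
               sample_id: str = "") -> RatioTrack:
    """Per-bin log2(ChIP/Input); missing where either side is missing or
    non-positive."""
    if not chip.same_binning(input_):
        raise ValueError("chip and input tracks have different binning")
    out: dict[str, np.ndarray] = {}
    for chrom in chip.values:
        c, i = chip.values[chrom], input_.values[chrom]
        valid = np.isfinite(c) & np.isfinite(i) & (i > 0) & (c > 0)
        res = np.full(len(c), np.nan)
        res[valid] = np.log2(c[valid] / i[valid])
        out[chrom] = res
    return RatioTrack(BinnedTrack(chip.bin_width, out, dict(chip.chrom_lengths)),
                      sample_id=sample_id)


def call_domains(ratio: RatioTrack, seed_percentile: float = 80.0,
                 stop_percentile: float = 30.0) -> list[K9Domain]:
    """Percentile-seeded domain calling.

    Thresholds are percentiles (linear interpolation) of all non-missing bins
    genome-wide.  Every maximal run of bins strictly above the stop threshold
    containing at least one bin above the seed threshold becomes one domain;
    a bin at or below the stop threshold, or a missing bin, terminates
    extension.  Domains are disjoint and sorted.
    """
    if seed_percentile <= stop_percentile:
        raise ValueError("seed_percentile must exceed stop_percentile")
    flat = ratio.track.all_values()
    if flat.size == 0:
        return []
    seed_thr = np.percentile(flat, seed_percentile)
    stop_thr = np.percentile(flat, stop_percentile)

    w = ratio.track.bin_width
    domains: list[K9Domain] = []
    for chrom in ratio.track.chroms:
        vals = ratio.track.values[chrom]
        extendable = np.isfinite(vals) & (vals > stop_thr)
        # maximal runs of extendable bins
        padded = np.concatenate(([False], extendable, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for lo, hi in zip(edges[::2], edges[1::2]):
            seg = vals[lo:hi]
            n_seeds = int(np.sum(seg > seed_thr))
            if n_seeds == 0:
                continue
            end_bp = min(hi * w, ratio.track.chrom_lengths.get(chrom, hi * w))
            domains.append(K9Domain(
                GenomicInterval(chrom, int(lo * w), int(end_bp),
                                name=f"K9_{chrom}_{lo}"),
                seed_bins=n_seeds, mean_ratio=float(np.mean(seg))))
    return domains


def fit_mixture(values: np.ndarray, seed: int | None = None,
                max_restarts: int = 5) -> MixtureFit:
    """Fit a two-component Gaussian mixture to log-ratio values by EM.

    Initialisation is k-means with a fixed seed for determinism; components
    are relabelled so component 2 has the higher mean.  A degenerate fit
    (components nearly coincident, or one nearly empty) raises
    :class:`DegenerateMixtureWarning`.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise ValueError("need >= 100 non-missing values for a mixture fit")
    x = values.reshape(-1, 1)

    last_exc: Exception | None = None
    for attempt in range(max_restarts):
        rs = (0 if seed is None else seed) + attempt
        try:
            gm = GaussianMixture(n_components=2, covariance_type="full",
                                 tol=1e-6, max_iter=500, n_init=1,
                                 init_params="kmeans", random_state=rs,
                                 reg_covar=1e-10).fit(x)
        except Exception as exc:  # variance collapse etc.
            last_exc = exc
            continue
        sigmas = np.sqrt(gm.covariances_.ravel())
        if np.all(sigmas > 1e-8):
            break
        last_exc = RuntimeError("variance collapse")
    else:
        raise RuntimeError(f"mixture fit failed after {max_restarts} restarts"
                           ) from last_exc

    order = np.argsort(gm.means_.ravel())  # component 2 = higher mean
    lam = gm.weights_.ravel()[order]
    mu = gm.means_.ravel()[order]
    sig = sigmas[order]
    fit = MixtureFit(lambdas=(float(lam[0]), float(lam[1])),
                     means=(float(mu[0]), float(mu[1])),
                     sigmas=(float(sig[0]), float(sig[1])),
                     log_likelihood=float(gm.score(x) * len(x)),
                     converged=bool(gm.converged_), n_bins=int(len(x)))
    separation = abs(mu[1] - mu[0])
    if min(lam) < 0.05 or separation < max(sig):
        warnings.warn("mixture components are poorly separated; the "
                      "signal-fraction estimate is unreliable",
                      DegenerateMixtureWarning, stacklevel=2)
    return fit


def genome_coverage_estimate(fit: MixtureFit) -> float:
    """Fraction of the genome in the signal component (lambda2)."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    return fit.lambda2


def scale_to_reference(tracks: Sequence[BinnedTrack],
                       fits: Sequence[MixtureFit],
                       ) -> tuple[list[BinnedTrack], list[float]]:
    """Scale depth-normalised tracks to the sample with the highest lambda2.

    Each track is multiplied by lambda2(track)/lambda2(reference), encoding
    relative global signal abundance; the reference (max lambda2) is
    unchanged and all factors are <= 1.
    """
    if len(tracks) != len(fits):
        raise ValueError("one fit per track required")
    lams = [f.lambda2 for f in fits]
    if any(l <= 0 for l in lams):
        raise ValueError("lambda2 must be positive for every track")
    ref = max(lams)
    factors = [l / ref for l in lams]
    scaled = []
    for t, f in zip(tracks, factors):
        s = t.copy()
        for chrom in s.values:
            s.values[chrom] = s.values[chrom] * f
        scaled.append(s)
    return scaled, factors


def domain_jaccard(called: Sequence[K9Domain],
                   truth: Sequence[GenomicInterval],
                   bin_width: int) -> float:
    """Bin-level Jaccard index between called and true domain sets."""
    def to_bins(intervals):
        bins = set()
        for iv in intervals:
            for b in range(iv.start // bin_width, -(-iv.end // bin_width)):
                bins.add((iv.chrom, b))
        return bins

    a = to_bins([d.interval for d in called])
    b = to_bins(truth)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
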