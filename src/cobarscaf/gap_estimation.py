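"""Gap size estimation from the Jaccard-similarity/distance relation.

Under random fragment generation and random read capture, the JS between two
bins decays with their genomic distance.  The decay is calibrated on the
input assembly's own long contigs, where bin-pair distances are known: bin
pairs are bucketed by centre-to-centre distance, bucket means are fitted
with an ordinary least-squares line over the range where the means are
strictly decreasing and above a noise floor, and the fitted line is inverted
to turn an edge's JS into a distance (then into a gap by subtracting the
half-bin offsets of the best bin pair).  Junctions established by paired-end
evidence alone get a fixed 11 bp gap — paired-end inserts are too short to
resolve the size any further.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .io_formats import ContigSet
from .prep import BinBarcodeIndex, jaccard_bins

PE_GAP_SIZE = 11  # bp, fixed for paired-end-derived junctions


@dataclass
class JSDistanceModel:
    """Linear JS(distance) model: js = intercept + slope * distance.

    Invertible only inside [js_lo, js_hi], the JS range spanned by the
    calibration buckets actually used for the fit (slope < 0 there).
    ``table`` keeps (bucket centre distance, mean JS, n pairs) for dumping.
    """

    intercept: float
    slope: float
    js_lo: float
    js_hi: float
    table: list[tuple[float, float, int]] = field(default_factory=list)

    def distance_for(self, js: float) -> float:
        return (js - self.intercept) / self.slope


def calibrate_js_distance(index: BinBarcodeIndex, contigs: ContigSet,
                          max_distance: int = 50_000,
                          bucket_width: int = 5000,
                          noise_floor: float = 0.02,
                          min_buckets: int = 3,
                          min_pairs_per_bucket: int = 100,
                          restrict_to: Optional[set[str]] = None,
                          ) -> JSDistanceModel:
    """Fit the empirical JS-versus-distance line on long contigs.

    Only full-size bins of contigs long enough to contain bin pairs up to
    ``max_distance`` apart contribute.  Because bins are chopped from both
    contig ends, some distance buckets collect only a handful of bin pairs;
    buckets below ``min_pairs_per_bucket`` carry too much sampling noise in
    their mean and are skipped.  Raises when too few long contigs (or too
    few usable buckets) exist — the caller should retry with a smaller
    ``max_distance``.
    """
    if bucket_width <= 0 or max_distance <= bucket_width:
        raise ValueError("need 0 < bucket_width < max_distance")
    n_buckets = max_distance // bucket_width
    sums = np.zeros(n_buckets)
    counts = np.zeros(n_buckets, dtype=int)
    usable = 0
    for contig in contigs:
        if restrict_to is not None and contig.id not in restrict_to:
            continue
        if contig.length < max_distance + index.bin_size:
            continue
        bins = [b for b in index.contig_bins(contig.id)
                if b.end - b.start == index.bin_size]
        usable += 1
        for i in range(len(bins)):
            for j in range(i + 1, len(bins)):
                d = abs(bins[j].center - bins[i].center)
                if d >= max_distance:
                    continue
                k = int(d // bucket_width)
                if k >= n_buckets:
                    continue
                sums[k] += jaccard_bins(bins[i].barcodes, bins[j].barcodes)
                counts[k] += 1
    if usable == 0:
        raise ValueError(
            f"no contigs of length >= {max_distance + index.bin_size} bp "
            "available for calibration; reduce max_distance")
    filled = counts >= max(1, min_pairs_per_bucket)
    centers = (np.arange(n_buckets) + 0.5) * bucket_width
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # usable range: strictly decreasing bucket means above the noise floor
    # (under-sampled buckets are skipped, not treated as a break)
    used: list[int] = []
    prev = np.inf
    for k in range(n_buckets):
        if not filled[k]:
            continue
        if means[k] >= prev or means[k] <= noise_floor:
            break
        used.append(k)
        prev = means[k]
    if len(used) < min_buckets:
        raise ValueError(
            "JS-distance calibration failed: fewer than "
            f"{min_buckets} strictly decreasing buckets above the noise "
            "floor; reduce max_distance or bucket_width")
    x = centers[used]
    y = means[used]
    fit = stats.linregress(x, y)
    # The decay is convex at both extremes (bins nearly on top of each other;
    # distances beyond most fragments), so the line is only trusted where its
    # residual is below half a bucket of distance-equivalent.  Trim the ends,
    # refit once on the trimmed range.
    for _ in range(2):
        if fit.slope >= 0:
            raise ValueError("JS-distance calibration produced a "
                             "non-negative slope; model not invertible")
        tol = abs(fit.slope) * bucket_width / 2.0
        resid = np.abs(y - (fit.intercept + fit.slope * x))
        lo, hi = 0, len(x)
        while hi - lo > min_buckets and resid[lo] > tol:
            lo += 1
        while hi - lo > min_buckets and resid[hi - 1] > tol:
            hi -= 1
        if lo == 0 and hi == len(x):
            break
        x, y = x[lo:hi], y[lo:hi]
        fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("JS-distance calibration produced a non-negative "
                         "slope; model not invertible")
    table = [(float(centers[k]), float(means[k]), int(counts[k]))
             for k in range(n_buckets) if filled[k]]
    return JSDistanceModel(intercept=float(fit.intercept),
                           slope=float(fit.slope),
                           js_lo=float(y[-1]), js_hi=float(y[0]),
                           table=table)


def estimate_gap(js: float, model: JSDistanceModel, gap_min: int = 1,
                 gap_max: int = 200_000, offset: float = 0.0) -> int:
    """Invert the calibrated line to turn an edge JS into a gap size.

    ``offset`` is the summed distance from each best bin's centre to the end
    of its contig that faces the gap, converting the modelled centre-to-
    centre distance into a gap.  JS above the invertible range means the
    contigs are as close as resolvable (``gap_min``); below it, farther than
    resolvable (``gap_max``).
    """
    if js >= model.js_hi:
        return gap_min
    if js <= model.js_lo:
        return gap_max
    gap = model.distance_for(js) - offset
    return int(min(max(round(gap), gap_min), gap_max))


def assign_pe_gap(pe_gap_size: int = PE_GAP_SIZE) -> int:
    """Fixed gap size for junctions constructed from paired-end evidence."""
    return pe_gap_size
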