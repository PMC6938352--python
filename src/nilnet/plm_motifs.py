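"""Preferentially located motif (PLM) detection in TSS-anchored promoters.

A motif's occurrence start positions are binned on the TSS-relative axis
(width-W bins anchored at -1000; default W=100, sized so that the any-bin
exceedance rule keeps a calibrated family-wise false-positive rate).  Per-bin
occurrence *rates* (count divided by the number of promoters covering the bin) over the distal background region
[-1000, -300) are fitted with an ordinary least-squares line in the bin
midpoint, and a 95% upper prediction bound

    U(x) = a x + b + t(0.975, m-2) * s * sqrt(1 + 1/m + (x - xbar)^2 / Sxx)

is formed.  The motif is a PLM iff some bin in the proximal search region
[-300, max UTR) with sufficient coverage has a rate above U at its midpoint;
the peak is the bin of maximal exceedance.

Matching is IUPAC-degenerate, overlapping occurrences are counted, N in a
sequence never matches, and scanning defaults to the promoter (forward)
strand with an option for both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import IUPAC, Motif, MotifLibrary, Promoter, PromoterSet, revcomp

BACKGROUND_REGION = (-1000, -300)
SEARCH_START = -300


class PLMError(ValueError):
    pass


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern.upper():
        if c not in IUPAC:
            raise PLMError(f"invalid IUPAC character {c!r}")
        s = IUPAC[c]
        parts.append(s if len(s) == 1 else f"[{s}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(promoter: Promoter, pattern: str, strands: str = "fwd") -> list[int]:
    """TSS-relative start positions of all (overlapping) IUPAC matches.

    For ``strands='both'``, reverse-complement matches are reported at the
    match's leftmost position on the promoter axis.
    """
    if strands not in ("fwd", "both"):
        raise PLMError("strands must be 'fwd' or 'both'")
    rx = _iupac_regex(pattern)
    seq = promoter.sequence
    hits = {m.start() for m in rx.finditer(seq)}
    if strands == "both":
        rx_rc = _iupac_regex(pattern)
        rc = revcomp(seq)
        L = len(seq)
        k = len(pattern)
        for m in rx_rc.finditer(rc):
            hits.add(L - m.start() - k)  # leftmost position on the fwd axis
    return sorted(h + promoter.start for h in hits)


@dataclass
class MotifOccurrenceProfile:
    motif: str
    bin_start: np.ndarray  # left edge of each width-W bin
    width: int
    counts: np.ndarray  # occurrences per bin, summed over promoters
    coverage: np.ndarray  # promoters whose extent spans the whole bin

    @property
    def midpoints(self) -> np.ndarray:
        return self.bin_start + self.width / 2.0

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.counts / self.coverage, np.nan)


def build_profile(occurrences: dict[str, list[int]], promoters: PromoterSet,
                  width: int = 100) -> MotifOccurrenceProfile:
    """Aggregate per-promoter occurrence positions into width-W bins anchored
    at -1000, spanning [-1000, max UTR)."""
    span = BACKGROUND_REGION[1] - BACKGROUND_REGION[0]
    if span % width:
        raise PLMError(f"bin width {width} must divide the {span} bp background region")
    max_end = promoters.max_utr
    n_bins = int(np.ceil((max_end + 1000) / width))
    starts = -1000 + width * np.arange(n_bins)
    counts = np.zeros(n_bins)
    coverage = np.zeros(n_bins, dtype=int)
    for p in promoters:
        lo = max(p.start, -1000)
        full = (starts >= lo) & (starts + width <= p.end)
        coverage[full] += 1
        for pos in occurrences.get(p.gene_id, ()):
            b = (pos + 1000) // width
            if 0 <= b < n_bins:
                counts[b] += 1
    return MotifOccurrenceProfile("", starts, width, counts, coverage)


@dataclass
class PLMModel:
    slope: float
    intercept: float
    resid_sd: float
    m: int  # number of background bins
    x_mean: float
    sxx: float

    def upper_bound(self, x: np.ndarray | float) -> np.ndarray | float:
        """95% upper prediction bound for a new bin rate at midpoint x."""
        tq = stats.t.ppf(0.975, df=self.m - 2)
        se = self.resid_sd * np.sqrt(1.0 + 1.0 / self.m + (x - self.x_mean) ** 2 / self.sxx)
        return self.slope * x + self.intercept + tq * se

    def line(self, x):
        return self.slope * x + self.intercept


def fit_background(profile: MotifOccurrenceProfile) -> PLMModel:
    """OLS of rate on bin midpoint over fully covered background bins."""
    mids = profile.midpoints
    in_bg = (profile.bin_start >= BACKGROUND_REGION[0]) & \
            (profile.bin_start + profile.width <= BACKGROUND_REGION[1])
    use = in_bg & (profile.coverage == profile.coverage[in_bg].max()) \
        if in_bg.any() else in_bg
    x = mids[use]
    y = profile.rates[use]
    m = x.size
    if m < 3:
        raise PLMError("need at least 3 fully covered background bins")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise PLMError("zero variance in background bin midpoints")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    resid_sd = float(np.sqrt(np.sum(resid**2) / (m - 2)))
    return PLMModel(slope, intercept, resid_sd, m, float(x.mean()), sxx)


@dataclass
class PLMResult:
    motif: str
    is_plm: bool
    peak_start: int | None  # left edge of the peak bin
    peak_rate: float
    bound_at_peak: float


def detect_plm(profile: MotifOccurrenceProfile, model: PLMModel,
               min_coverage_fraction: float = 0.5) -> PLMResult:
    """Flag the motif if any search-region bin with adequate coverage has a
    rate above the background upper bound."""
    n_prom = int(profile.coverage.max(initial=0))
    search = profile.bin_start >= SEARCH_START
    if not search.any():
        raise PLMError("empty search region")
    eligible = search & (profile.coverage >= min_coverage_fraction * n_prom) & \
        (profile.coverage > 0)
    if not eligible.any():
        return PLMResult(profile.motif, False, None, 0.0, 0.0)
    mids = profile.midpoints[eligible]
    rates = profile.rates[eligible]
    bounds = np.asarray(model.upper_bound(mids), dtype=float)
    exceed = rates - bounds
    k = int(np.argmax(exceed))
    is_plm = bool(exceed[k] > 0)
    peak = int(profile.bin_start[eligible][k])
    return PLMResult(profile.motif, is_plm, peak if is_plm else None,
                     float(rates[k]), float(bounds[k]))


def run_plm(promoters: PromoterSet, motifs: MotifLibrary, width: int = 100,
            strands: str = "fwd",
            min_coverage_fraction: float = 0.5) -> list[PLMResult]:
    """Scan -> profile -> background fit -> detection for every motif."""
    if len(promoters) == 0:
        raise PLMError("no promoters left after the UTR filter")
    if len(motifs) == 0:
        raise PLMError("empty motif library")
    results = []
    for motif in motifs:
        occ = {p.gene_id: scan_motif(p, motif.pattern, strands) for p in promoters}
        profile = build_profile(occ, promoters, width)
        profile.motif = motif.name
        model = fit_background(profile)
        results.append(detect_plm(profile, model, min_coverage_fraction))
    return results
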