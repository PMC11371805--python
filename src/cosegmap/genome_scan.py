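"""Sliding-window co-segregation proportion scans and interval calling.

The genome-wide scan follows the mapping design's two scales: a coarse pass
over every scaffold longer than 1 Mb with 1 Mb windows stepping by 100 kb
(SNP/MNP sites only), and a fine pass over one scaffold with 200 kb windows
stepping by 50 kb (indels included).  Each window reports the proportion of
its informative sites that co-segregate with the phenotype; windows with no
informative site carry an undefined (NA) proportion rather than zero, since
0/0 is not evidence against linkage.

A site belongs to every window containing its start coordinate; windows are
anchored at coordinate 0 of each scaffold and the trailing window is
clipped at the scaffold end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .coseg_classifier import COSEG, NON_COSEG, SiteStatus
from .errors import NoInformativeWindowsError, ValidationError

__all__ = [
    "ScanWindow",
    "CandidateInterval",
    "scan",
    "fine_scan",
    "call_interval",
    "plot_scan",
]

GENOME_CLASSES = frozenset({"SNP", "MNP"})
FINE_CLASSES = frozenset({"SNP", "MNP", "indel"})


@dataclass(frozen=True)
class ScanWindow:
    """One genomic window with its co-segregation proportion (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    n_informative: int
    n_coseg: int

    @property
    def proportion(self) -> Optional[float]:
        if self.n_informative == 0:
            return None
        return self.n_coseg / self.n_informative


@dataclass(frozen=True)
class CandidateInterval:
    """Candidate region called from the window scan."""

    scaffold: str
    start: int
    end: int
    peak_proportion: float
    n_coseg_inside: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("interval start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length / 1e6


def _statuses_to_frame(statuses) -> pd.DataFrame:
    if isinstance(statuses, pd.DataFrame):
        return statuses
    rows = [
        (s.scaffold, s.pos, s.vclass, s.status)
        for s in statuses
    ]
    return pd.DataFrame(rows, columns=["scaffold", "pos", "vclass", "status"])


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if length <= window:
        return np.array([0])
    last = int(np.ceil((length - window) / step)) * step
    return np.arange(0, last + 1, step)


def scan(
    statuses: Iterable[SiteStatus] | pd.DataFrame,
    scaffold_lengths: Dict[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
    min_scaffold: int = 1_000_000,
    variant_classes: Set[str] = GENOME_CLASSES,
) -> List[ScanWindow]:
    """Genome-wide windowed proportion of co-segregating informative sites.

    Scaffolds of length <= ``min_scaffold`` are excluded; scaffold order
    follows ``scaffold_lengths`` insertion order.  Raises if positions are
    not sorted within a scaffold.
    """
    frame = _statuses_to_frame(statuses)
    frame = frame[frame["vclass"].isin(variant_classes)]
    windows: List[ScanWindow] = []
    for scaffold, length in scaffold_lengths.items():
        if length <= min_scaffold:
            continue
        sub = frame[frame["scaffold"] == scaffold]
        pos = sub["pos"].to_numpy()
        if len(pos) and np.any(np.diff(pos) < 0):
            raise ValidationError(
                f"positions on {scaffold} are not sorted; sort the input by position"
            )
        status = sub["status"].to_numpy()
        informative_pos = pos[(status == COSEG) | (status == NON_COSEG)]
        coseg_pos = pos[status == COSEG]
        starts = _window_starts(length, window, step)
        ends = np.minimum(starts + window, length)
        n_inf = np.searchsorted(informative_pos, ends, side="left") - np.searchsorted(
            informative_pos, starts, side="left"
        )
        n_cs = np.searchsorted(coseg_pos, ends, side="left") - np.searchsorted(
            coseg_pos, starts, side="left"
        )
        for s, e, ni, nc in zip(starts, ends, n_inf, n_cs):
            windows.append(ScanWindow(scaffold, int(s), int(e), int(ni), int(nc)))
    return windows


def fine_scan(
    statuses: Iterable[SiteStatus] | pd.DataFrame,
    scaffold: str,
    scaffold_length: int,
    window: int = 200_000,
    step: int = 50_000,
    variant_classes: Set[str] = FINE_CLASSES,
) -> List[ScanWindow]:
    """Fine-scale scan of a single scaffold, indels included by default."""
    frame = _statuses_to_frame(statuses)
    frame = frame[frame["scaffold"] == scaffold]
    return scan(
        frame,
        {scaffold: scaffold_length},
        window=window,
        step=step,
        min_scaffold=0,
        variant_classes=variant_classes,
    )


def call_interval(
    windows: Sequence[ScanWindow],
    frac_of_peak: float = 0.9,
    min_informative: int = 10,
) -> CandidateInterval:
    """Call the candidate interval around the global proportion peak.

    The peak is the window with the highest defined proportion among
    windows with at least ``min_informative`` informative sites (ties:
    larger coseg count, then input order).  The interval is the union of
    the maximal contiguous run of qualifying windows (proportion >=
    ``frac_of_peak`` x peak, informative count met) containing the peak, on
    the peak's scaffold.  Deterministic and idempotent given its inputs.
    """
    eligible = [
        (i, w)
        for i, w in enumerate(windows)
        if w.proportion is not None and w.n_informative >= min_informative
    ]
    if not eligible:
        raise NoInformativeWindowsError(
            "no informative windows: every window proportion is NA "
            "or below the informative-site minimum"
        )
    peak_i, peak = max(eligible, key=lambda t: (t[1].proportion, t[1].n_coseg, -t[0]))
    threshold = frac_of_peak * peak.proportion

    on_scaffold = sorted(
        (w for w in windows if w.scaffold == peak.scaffold), key=lambda w: w.start
    )
    qualifies = [
        w.proportion is not None
        and w.n_informative >= min_informative
        and w.proportion >= threshold
        for w in on_scaffold
    ]
    k = on_scaffold.index(peak)
    lo = k
    while lo > 0 and qualifies[lo - 1]:
        lo -= 1
    hi = k
    while hi + 1 < len(on_scaffold) and qualifies[hi + 1]:
        hi += 1
    run = on_scaffold[lo : hi + 1]

    # distinct-site coseg count via a greedy disjoint subcover of the run
    n_coseg = 0
    cover_end = run[0].start
    for w in run:
        if w.start >= cover_end:
            n_coseg += w.n_coseg
            cover_end = w.end
    return CandidateInterval(
        scaffold=peak.scaffold,
        start=run[0].start,
        end=run[-1].end,
        peak_proportion=peak.proportion,
        n_coseg_inside=n_coseg,
    )


def plot_scan(windows: Sequence[ScanWindow], ax=None, scaffold_order=None):
    """Plot window proportions per scaffold, longest scaffold first.

    Mirrors the usual genome-scan layout: x is cumulative genome position,
    scaffolds alternately coloured. Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    spans: Dict[str, int] = {}
    for w in windows:
        spans[w.scaffold] = max(spans.get(w.scaffold, 0), w.end)
    if scaffold_order is None:
        scaffold_order = sorted(spans, key=lambda s: -spans[s])
    offsets = {}
    acc = 0
    for s in scaffold_order:
        offsets[s] = acc
        acc += spans[s]
    for i, s in enumerate(scaffold_order):
        xs = [
            offsets[s] + (w.start + w.end) / 2
            for w in windows
            if w.scaffold == s and w.proportion is not None
        ]
        ys = [w.proportion for w in windows if w.scaffold == s and w.proportion is not None]
        ax.plot(xs, ys, ".", ms=3, color="black" if i % 2 == 0 else "red", label=None)
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel("co-segregating proportion")
    ax.set_ylim(-0.02, 1.02)
    return ax
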