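"""In-silico restriction digestion, tag extraction and fragment spectra.

The digestion model underpinning reduced-representation (GBS/RAD-style)
library simulation: scan each chromosome for recognition sites (IUPAC
degeneracy honoured, overlapping matches included), cut the sequence into
fragments, keep the subset a given library protocol can amplify, and read
off the fixed-length sequence tags flanking each cut.  Fragment size and
GC-content spectra summarise what a sequencing library drawn from those
fragments should look like in the absence of amplification bias.

Coordinates are 0-based half-open; cut positions refer to the top strand.
This module is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .enzymes import IUPAC, RestrictionEnzyme, reverse_complement

#: Sentinel boundary label for fragments that end at a chromosome end.
CHROM_END = "CHROM_END"


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All cut positions of ``enzyme`` in ``sequence``.

    Returns the sorted, de-duplicated list of ``match_start + cut_offset``
    over every (possibly overlapping) recognition-site match on the top
    strand.  Only palindromic enzymes are accepted (enforced at enzyme
    construction), so top-strand scanning is complete.
    """
    sequence = sequence.upper()
    site = enzyme.recognition
    m = len(site)
    allowed = [IUPAC[c] for c in site]
    cuts = set()
    for start in range(len(sequence) - m + 1):
        if all(sequence[start + i] in allowed[i] for i in range(m)):
            cuts.add(start + enzyme.cut_offset)
    return sorted(cuts)


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: a genome interval between two cuts.

    ``left_enzyme``/``right_enzyme`` name the enzyme that produced each
    boundary, or :data:`CHROM_END` for chromosome ends.
    """

    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment {self.chrom}:{self.start}-{self.end}")
        if len(self.sequence) != self.length:
            raise ValueError("fragment sequence length disagrees with interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class Tag:
    """A fixed-length sequence tag read inward from one fragment end.

    Right-side tags are reverse-complemented into read orientation so that
    every tag starts at its cut site.
    """

    fragment_id: str
    side: Literal["left", "right"]
    sequence: str


def digest(
    sequences: dict[str, str],
    enzymes: Sequence[RestrictionEnzyme],
) -> list[Fragment]:
    """Digest a set of chromosome sequences with one or more enzymes.

    Cuts from all enzymes are merged per chromosome; fragments are the
    intervals between consecutive cuts plus the two chromosome-end pieces.
    The concatenation of fragment sequences reproduces each chromosome
    exactly.  If two enzymes cut at the same coordinate the boundary is
    labelled with the alphabetically first enzyme name (deterministic
    tie-break).
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    fragments: list[Fragment] = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        if not seq:
            continue
        cut_label: dict[int, str] = {}
        for enz in sorted(enzymes, key=lambda e: e.name):
            for pos in find_sites(seq, enz):
                cut_label.setdefault(pos, enz.name)
        # interior cuts only: a cut at 0 or len(seq) produces no new boundary
        cuts = sorted(p for p in cut_label if 0 < p < len(seq))
        bounds = [0, *cuts, len(seq)]
        labels = [CHROM_END, *(cut_label[p] for p in cuts), CHROM_END]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            fragments.append(
                Fragment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    left_enzyme=labels[i],
                    right_enzyme=labels[i + 1],
                    sequence=seq[start:end],
                )
            )
    return fragments


Protocol = Literal["single", "double_different_ends"]


def select_amplifiable(
    fragments: Iterable[Fragment], protocol: Protocol
) -> list[Fragment]:
    """Fragments a library protocol can PCR-amplify.

    ``single`` (one frequent cutter, ApeKI-style): both ends must carry an
    enzyme cut — chromosome-end fragments have no adapter on one side and
    are dropped.  ``double_different_ends`` (PstI:MspI-style): the two ends
    must be cut by two *different* enzymes, since the common adapter only
    supports amplification of such fragments.
    """
    frags = list(fragments)
    if protocol == "single":
        return [
            f
            for f in frags
            if f.left_enzyme != CHROM_END and f.right_enzyme != CHROM_END
        ]
    if protocol == "double_different_ends":
        return [
            f
            for f in frags
            if f.left_enzyme != CHROM_END
            and f.right_enzyme != CHROM_END
            and f.left_enzyme != f.right_enzyme
        ]
    raise ValueError(f"unknown protocol {protocol!r}")


def fragment_id(f: Fragment) -> str:
    return f"{f.chrom}:{f.start}-{f.end}"


def extract_tags(fragment: Fragment, tag_length: int = 64) -> list[Tag]:
    """The 1-2 sequence tags of an amplifiable fragment.

    One tag per end, spanning ``tag_length`` bases inward from the cut; the
    right-end tag is reverse-complemented into read orientation.  Fragments
    shorter than ``tag_length`` follow the truncate-to-insert policy: each
    tag is the whole insert (no N-padding), and because the two tags are
    then exact reverse complements of each other, only the left one is kept.
    """
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    fid = fragment_id(fragment)
    left = Tag(fid, "left", fragment.sequence[:tag_length])
    if fragment.length <= tag_length:
        return [left]
    right = Tag(fid, "right", reverse_complement(fragment.sequence[-tag_length:]))
    return [left, right]


@dataclass(frozen=True)
class BinSpec:
    """Ordered bin edges for fragment-size or GC-content spectra.

    ``n`` edges define ``n - 1`` bins ``[e0,e1), [e1,e2), ...``; the last
    bin is closed on the right and, when ``open_last`` is set, absorbs any
    value beyond the final edge (an open-ended ">last" class).
    """

    edges: tuple[float, ...]
    open_last: bool = True

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least two bin edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        labs = [
            f"[{self.edges[i]:g},{self.edges[i+1]:g})" for i in range(self.n_bins)
        ]
        if self.open_last:
            labs[-1] = f">={self.edges[-2]:g}"
        return labs

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index for each value (values above the last edge go to the
        last bin when open-ended; below the first edge is an error)."""
        values = np.asarray(values, dtype=float)
        if np.any(values < self.edges[0]):
            raise ValueError("value below the first bin edge")
        idx = np.searchsorted(self.edges, values, side="right") - 1
        if self.open_last:
            idx = np.minimum(idx, self.n_bins - 1)
        elif np.any(idx >= self.n_bins) and np.any(values > self.edges[-1]):
            raise ValueError("value above the final bin edge (closed binning)")
        else:
            idx = np.minimum(idx, self.n_bins - 1)  # value == last edge
        return idx


#: 15 fragment-size classes: 100-bp bins from 0 to 1400 plus an open >1400 class.
DEFAULT_SIZE_BINS = BinSpec(tuple(float(x) for x in range(0, 1500, 100)) + (math.inf,))

#: 7 GC-content classes with 0.35 as an edge: open ends below 0.15 / above 0.65.
DEFAULT_GC_BINS = BinSpec((0.0, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 1.0), open_last=False)


@dataclass
class TagDistribution:
    """Per-bin relative frequencies of a fragment/tag spectrum."""

    binspec: BinSpec
    counts: np.ndarray = field(repr=False)

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.binspec.labels(),
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


def spectrum(
    fragments: Sequence[Fragment],
    binspec: BinSpec,
    by: Literal["length", "gc"] = "length",
    weights: Sequence[float] | None = None,
) -> TagDistribution:
    """Histogram of fragment sizes or GC fractions over ``binspec``.

    ``weights`` lets observed read counts stand in for plain fragment
    counts (one entry per fragment).
    """
    values = np.array(
        [f.length if by == "length" else f.gc_fraction for f in fragments],
        dtype=float,
    )
    counts = np.zeros(binspec.n_bins)
    if len(values):
        idx = binspec.assign(values)
        w = np.ones_like(values) if weights is None else np.asarray(weights, float)
        np.add.at(counts, idx, w)
    return TagDistribution(binspec, counts)


def observed_vs_expected(
    observed: TagDistribution, expected: TagDistribution
) -> pd.DataFrame:
    """Per-bin observed vs expected percentages and their signed deviation.

    Both spectra must share the same bins; deviations sum to zero by
    construction (both percentage columns sum to 100).
    """
    if observed.binspec != expected.binspec:
        raise ValueError("observed and expected spectra use different bins")
    obs = observed.frequencies * 100.0
    exp = expected.frequencies * 100.0
    return pd.DataFrame(
        {
            "bin": observed.binspec.labels(),
            "observed_pct": obs,
            "expected_pct": exp,
            "deviation_pct": obs - exp,
        }
    )


def fragments_to_frame(fragments: Sequence[Fragment]) -> pd.DataFrame:
    """BED-like table of fragments (chrom, start, end, boundary enzymes, length, gc)."""
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "left_enzyme": [f.left_enzyme for f in fragments],
            "right_enzyme": [f.right_enzyme for f in fragments],
            "length": [f.length for f in fragments],
            "gc": [f.gc_fraction for f in fragments],
        }
    )
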