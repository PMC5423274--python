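"""Read allocation across sequence tags under polymerase amplification bias.

Models the multiplexed sequencing step of a reduced-representation library:
every genotype receives a fixed read budget, and reads fall on the
amplifiable tags with probabilities proportional to per-fragment
amplification weights.  Weights factorise into a fragment-size kernel (a
log-normal bump: PCR favours an intermediate size range) and a GC-content
logistic (some polymerases over-amplify GC-rich fragments).  Presets:

``uniform``
    no bias; every tag equally likely.
``kapa_like``
    nearly flat over size and GC — a polymerase with uniform amplification.
``neb_like``
    enriches 100-500 bp fragments and fragments with GC above 35% —
    a selective polymerase.

The presets are qualitative (sign-testable) calibrations; no parametric
bias fit is implied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import (
    Fragment,
    Tag,
    digest,
    extract_tags,
    select_amplifiable,
)
from .enzymes import RestrictionEnzyme


@dataclass(frozen=True)
class BiasModel:
    """Multiplicative size x GC amplification-bias model.

    size weight: ``base + amp * exp(-(ln L - ln center)^2 / (2 sigma^2))``
    gc weight:   ``low + (high - low) / (1 + exp(-(gc - mid) / width))``

    All weights are strictly positive as long as ``base > 0`` (or
    ``amp >= 0``) and ``low > 0``.
    """

    name: str
    size_center: float = 300.0
    size_sigma: float = 0.8       # ln-length units
    size_amp: float = 0.0         # 0 -> flat in size
    size_base: float = 1.0
    gc_low: float = 1.0
    gc_high: float = 1.0          # == gc_low -> flat in GC
    gc_mid: float = 0.35
    gc_width: float = 0.05

    def size_weight(self, length: np.ndarray) -> np.ndarray:
        length = np.asarray(length, dtype=float)
        z = (np.log(length) - np.log(self.size_center)) / self.size_sigma
        return self.size_base + self.size_amp * np.exp(-0.5 * z * z)

    def gc_weight(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        return self.gc_low + (self.gc_high - self.gc_low) / (
            1.0 + np.exp(-(gc - self.gc_mid) / self.gc_width)
        )

    def weight(self, length: np.ndarray, gc: np.ndarray) -> np.ndarray:
        w = self.size_weight(length) * self.gc_weight(gc)
        if np.any(w <= 0):
            raise ValueError(f"bias model {self.name!r} produced non-positive weights")
        return w


UNIFORM = BiasModel("uniform")
KAPA_LIKE = BiasModel(
    "kapa_like", size_amp=0.15, size_base=1.0, gc_low=0.95, gc_high=1.05
)
NEB_LIKE = BiasModel(
    "neb_like", size_center=250.0, size_sigma=0.6, size_amp=3.0, size_base=0.3,
    gc_low=0.6, gc_high=1.6,
)

BIAS_PRESETS: dict[str, BiasModel] = {
    b.name: b for b in (UNIFORM, KAPA_LIKE, NEB_LIKE)
}


class DepthTable:
    """Tag x genotype matrix of read depths.

    Wraps a :class:`pandas.DataFrame` (tags in rows, genotypes in columns)
    with the fragments each tag came from, so spectra of *observed* reads
    can be compared with in-silico expectations.
    """

    def __init__(
        self,
        depths: pd.DataFrame,
        tags: Sequence[Tag] | None = None,
        fragments: Sequence[Fragment] | None = None,
    ):
        if (depths.to_numpy() < 0).any():
            raise ValueError("read depths must be non-negative")
        self.depths = depths
        self.tags = list(tags) if tags is not None else None
        self.fragments = list(fragments) if fragments is not None else None

    @property
    def n_tags(self) -> int:
        return self.depths.shape[0]

    @property
    def genotypes(self) -> list[str]:
        return list(self.depths.columns)

    def column_totals(self) -> pd.Series:
        return self.depths.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.depths.to_csv(path, sep="\t", index_label="tag")

    @classmethod
    def from_tsv(cls, path) -> "DepthTable":
        return cls(pd.read_csv(path, sep="\t", index_col="tag"))


def amplification_weights(
    fragments: Sequence[Fragment], bias: BiasModel, tags_per_fragment: Sequence[int] | None = None
) -> np.ndarray:
    """Normalised per-tag sampling weights under a bias model.

    Each amplifiable fragment contributes one weight per tag it yields
    (``tags_per_fragment``, default 2 for fragments longer than the tag and
    1 otherwise is the caller's concern — default here is one entry per
    fragment); weights are ``size_weight x gc_weight`` normalised to sum 1.
    """
    if not len(fragments):
        raise ValueError("no fragments to weight")
    lengths = np.array([f.length for f in fragments], dtype=float)
    gcs = np.array([f.gc_fraction for f in fragments], dtype=float)
    w = bias.weight(lengths, gcs)
    if tags_per_fragment is not None:
        w = np.repeat(w, np.asarray(tags_per_fragment, dtype=int))
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total amplification weight")
    return w / total


def sample_read_depths(
    weights: np.ndarray,
    total_reads: int,
    n_genotypes: int,
    rng: np.random.Generator,
    genotype_names: Sequence[str] | None = None,
    tag_index: Sequence[str] | None = None,
) -> DepthTable:
    """Independent multinomial read allocation per genotype.

    Every genotype receives exactly ``total_reads`` reads distributed over
    tags with probability ``weights`` (column sums are exact — read
    conservation).
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    names = (
        list(genotype_names)
        if genotype_names is not None
        else [f"g{i}" for i in range(n_genotypes)]
    )
    mat = np.stack(
        [rng.multinomial(total_reads, weights) for _ in range(n_genotypes)], axis=1
    )
    index = list(tag_index) if tag_index is not None else list(range(len(weights)))
    return DepthTable(pd.DataFrame(mat, index=index, columns=names))


def downsample(
    depth_column: np.ndarray, target_total: int, rng: np.random.Generator
) -> np.ndarray:
    """Thin one genotype's depths to ``target_total`` reads without replacement.

    Hypergeometric (multivariate) thinning: reads are removed uniformly at
    random, so each tag's expected depth scales by ``target/current``.
    """
    col = np.asarray(depth_column, dtype=np.int64)
    current = int(col.sum())
    if target_total > current:
        raise ValueError(f"target {target_total} exceeds current total {current}")
    if target_total == current:
        return col.copy()
    return rng.multivariate_hypergeometric(col, target_total)


def tags_at_depth(depth_column: np.ndarray, min_depth: int) -> int:
    """Number of tags with read depth >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return int((np.asarray(depth_column) >= min_depth).sum())


def run_protocol_comparison(
    sequences: dict[str, str],
    protocols: dict[str, tuple[Sequence[RestrictionEnzyme], str]],
    bias: BiasModel,
    read_budgets: Sequence[int],
    thresholds: Sequence[int] = (2, 6, 11),
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Tag counts per (protocol, read budget, depth threshold, replicate).

    ``protocols`` maps a protocol name to ``(enzymes, amplification_mode)``
    where the mode is ``"single"`` or ``"double_different_ends"``.  For each
    protocol the genome is digested once; each replicate draws a fresh
    multinomial read allocation of the budget over the protocol's tags and
    counts tags at or above each depth threshold — the in-silico analogue
    of comparing library protocols at a fixed per-genotype sequencing
    effort.
    """
    if not protocols:
        raise ValueError("empty protocol list")
    rng = np.random.default_rng(seed)
    rows = []
    for pname, (enzymes, mode) in protocols.items():
        frags = select_amplifiable(digest(sequences, enzymes), mode)
        if not frags:
            raise ValueError(f"protocol {pname!r}: no amplifiable fragments")
        n_tags_per = [len(extract_tags(f)) for f in frags]
        weights = amplification_weights(frags, bias, tags_per_fragment=n_tags_per)
        for budget in read_budgets:
            for rep in range(reps):
                col = rng.multinomial(budget, weights)
                for thr in thresholds:
                    rows.append(
                        {
                            "protocol": pname,
                            "budget": budget,
                            "threshold": thr,
                            "rep": rep,
                            "n_tags": tags_at_depth(col, thr),
                            "mean_depth": budget / len(weights),
                        }
                    )
    return pd.DataFrame(rows)
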