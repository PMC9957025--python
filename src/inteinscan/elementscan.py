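"""Detection of insertion elements as low-occupancy alignment blocks.

An insertion element (intein, homing endonuclease, accessory domain) that
invaded only part of a protein family shows up in the family alignment as a
run of columns where most rows are gaps — only the carriers have residues —
flanked on both sides by well-occupied (conserved host) columns.  The scan
finds maximal such runs; patchiness itself is the signal, so occupancy is
computed over *all* rows, not over carriers.

Also provides a shuffle-based significance test for pairwise similarity:
the local alignment score of two sequences is compared with the score
distribution against shuffled partners, yielding a Z-score and an
extreme-value E-value estimate (the expected number of equally good matches
in ``n_ref`` shuffled comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from .alnio import GAP, Alignment


@dataclass(frozen=True)
class InsertionElement:
    """A detected low-occupancy block and its carriers."""

    name: str
    block: tuple[int, int]           # 0-based half-open column interval
    carriers: frozenset[str]
    occupancy: float                 # mean non-gap fraction inside the block
    flank_occupancy: float           # mean over flank_width columns each side

    def __post_init__(self) -> None:
        if self.block[0] >= self.block[1]:
            raise ValueError("empty block")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy outside [0, 1]")
        if not self.carriers:
            raise ValueError("element without carriers")


@dataclass(frozen=True)
class ShuffleTestResult:
    raw_score: float
    shuffle_mean: float
    shuffle_sd: float
    z: float
    e_value_estimate: float
    n_shuffles: int
    seed: int


class DegenerateShuffleError(ValueError):
    """All shuffle scores identical; no Z-score is defined."""


def _occupancy_profile(alignment: Alignment) -> np.ndarray:
    mat = np.array([list(alignment.rows[i]) for i in alignment.ids])
    return (mat != GAP).mean(axis=0)


def scan_insertions(alignment: Alignment, max_occupancy: float = 0.5,
                    min_block_len: int = 30, flank_occupancy_min: float = 0.8,
                    flank_width: int = 10, min_carriers: int = 2,
                    min_span: float = 0.5) -> list[InsertionElement]:
    """Find insertion elements as gappy column blocks with conserved flanks.

    A block is a maximal run of >= ``min_block_len`` consecutive columns with
    occupancy <= ``max_occupancy`` whose ``flank_width`` columns on each side
    average occupancy >= ``flank_occupancy_min``.  Carriers are the rows with
    >= ``min_span`` non-gap fraction inside the block.  Blocks are named
    ``element_1``, ``element_2``, ... by position.
    """
    if alignment.n_seqs == 0:
        raise ValueError("empty alignment")
    if not (0.0 < max_occupancy < flank_occupancy_min <= 1.0):
        raise ValueError("need 0 < max_occupancy < flank_occupancy_min <= 1")
    L = alignment.n_columns
    if L < 2 * flank_width + min_block_len:
        raise ValueError(
            f"alignment of {L} columns too short for flank_width={flank_width}, "
            f"min_block_len={min_block_len}"
        )
    occ = _occupancy_profile(alignment)
    low = occ <= max_occupancy
    out: list[InsertionElement] = []
    i = 0
    while i < L:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < L and low[j]:
            j += 1
        # maximal run [i, j)
        if (j - i) >= min_block_len and i >= flank_width and j + flank_width <= L:
            left = occ[i - flank_width:i].mean()
            right = occ[j:j + flank_width].mean()
            if left >= flank_occupancy_min and right >= flank_occupancy_min:
                carriers = []
                for sid in alignment.ids:
                    seg = alignment.rows[sid][i:j]
                    if 1.0 - seg.count(GAP) / (j - i) >= min_span:
                        carriers.append(sid)
                if len(carriers) >= min_carriers:
                    out.append(InsertionElement(
                        name=f"element_{len(out) + 1}",
                        block=(i, j),
                        carriers=frozenset(carriers),
                        occupancy=float(occ[i:j].mean()),
                        flank_occupancy=float((left + right) / 2.0),
                    ))
        i = j
    return out


def carrier_lengths(element: InsertionElement, alignment: Alignment) -> dict[str, int]:
    """Ungapped element length (residues) per carrier."""
    s, e = element.block
    if e > alignment.n_columns:
        raise ValueError("element block outside alignment")
    return {
        sid: (e - s) - alignment.rows[sid][s:e].count(GAP)
        for sid in alignment.ids if sid in element.carriers
    }


def extract_element_sequences(element: InsertionElement,
                              alignment: Alignment) -> dict[str, str]:
    """Ungapped element subsequences per carrier."""
    s, e = element.block
    if e > alignment.n_columns:
        raise ValueError("element block outside alignment")
    return {
        sid: alignment.rows[sid][s:e].replace(GAP, "")
        for sid in alignment.ids if sid in element.carriers
    }


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def shuffle_significance(seq_a: str, seq_b: str, n_shuffles: int = 1000,
                         n_ref: int = 10_000, seed: int = 0) -> ShuffleTestResult:
    """Shuffle test of pairwise local-alignment similarity.

    ``seq_b`` is uniformly permuted ``n_shuffles`` times; the Z-score places
    the unshuffled score within the shuffle distribution, and the E-value is
    ``n_ref * P(score >= raw)`` under a Gumbel fit to the shuffle scores —
    the expected number of equally good matches among ``n_ref`` comparisons
    with shuffled sequences.
    """
    if len(seq_a) < 10 or len(seq_b) < 10:
        raise ValueError("sequences must be at least 10 residues")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    aligner = _local_aligner()
    raw = float(aligner.score(seq_a, seq_b))
    rng = np.random.default_rng(seed)
    b = np.array(list(seq_b))
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        scores[k] = aligner.score(seq_a, "".join(rng.permutation(b)))
    mean, sd = float(scores.mean()), float(scores.std(ddof=1))
    if sd == 0.0:
        raise DegenerateShuffleError("shuffle score distribution is degenerate")
    z = (raw - mean) / sd
    loc, scale = gumbel_r.fit(scores)
    e_value = float(n_ref * gumbel_r.sf(raw, loc=loc, scale=scale))
    return ShuffleTestResult(raw_score=raw, shuffle_mean=mean, shuffle_sd=sd,
                             z=z, e_value_estimate=e_value,
                             n_shuffles=n_shuffles, seed=seed)
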