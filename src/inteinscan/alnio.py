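"""Alignment and metadata I/O, site sets, and extein/element partitions.

A protein family invaded by mobile insertion elements (inteins, homing
endonucleases, uncharacterised domains) is analysed column-wise: the host
("extein") columns and each element's column block are separated into named
site sets, and per-element partitions restricted to the carrier sequences
feed the downstream phylogenetics.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = set(AMINO_ACIDS) | {"X", GAP}


class FastaFormatError(ValueError):
    """Raised for duplicate ids, illegal characters or ragged aligned input."""


class EmptyPartitionError(ValueError):
    """Raised when a partition would contain no rows or no columns."""


@dataclass
class Alignment:
    """An aligned (or, when ``aligned=False``, ragged) set of protein sequences.

    Parameters
    ----------
    ids:
        Sequence identifiers in input order; must be unique.
    rows:
        id -> residue string over the 20 amino acids, ``X`` and ``-``.
    labels:
        Optional id -> cluster-or-singleton label.
    aligned:
        When True all rows must share a common length.
    """

    ids: list[str]
    rows: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)
    aligned: bool = True

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FastaFormatError(f"duplicate sequence ids: {dupes}")
        lengths = {len(self.rows[i]) for i in self.ids}
        if self.aligned and len(lengths) > 1:
            raise FastaFormatError(f"unequal aligned row lengths: {sorted(lengths)}")
        for sid in self.ids:
            row = self.rows[sid]
            for pos, ch in enumerate(row):
                if ch not in _ALPHABET:
                    raise FastaFormatError(
                        f"illegal character {ch!r} in sequence {sid!r} at position {pos}"
                    )

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        if not self.aligned:
            raise ValueError("unaligned sequence set has no common column count")
        return len(self.rows[self.ids[0]]) if self.ids else 0

    def row(self, sid: str) -> str:
        return self.rows[sid]

    def subset_rows(self, keep: Iterable[str]) -> "Alignment":
        keep = set(keep)
        ids = [i for i in self.ids if i in keep]
        return Alignment(
            ids=ids,
            rows={i: self.rows[i] for i in ids},
            labels={i: self.labels[i] for i in ids if i in self.labels},
            aligned=self.aligned,
        )

    def ungapped(self, sid: str) -> str:
        return self.rows[sid].replace(GAP, "")


@dataclass(frozen=True)
class SiteSet:
    """A named, sorted set of 0-based alignment column indices."""

    name: str
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = self.columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError(f"site set {self.name!r}: columns must be strictly increasing")
        if cols and cols[0] < 0:
            raise ValueError(f"site set {self.name!r}: negative column index")

    def __len__(self) -> int:
        return len(self.columns)

    def blocks(self) -> list[tuple[int, int]]:
        """Contiguous runs as 0-based half-open (start, end) intervals."""
        out: list[tuple[int, int]] = []
        for c in self.columns:
            if out and c == out[-1][1]:
                out[-1] = (out[-1][0], c + 1)
            else:
                out.append((c, c + 1))
        return out

    @classmethod
    def from_blocks(cls, name: str, blocks: Iterable[tuple[int, int]]) -> "SiteSet":
        cols: list[int] = []
        for start, end in blocks:
            cols.extend(range(start, end))
        return cls(name, tuple(sorted(cols)))


@dataclass
class Partition:
    """An alignment restricted to one site set (and optionally to carriers)."""

    name: str
    alignment: Alignment
    site_set: SiteSet
    carriers_only: bool = False
    dropped_ids: tuple[str, ...] = ()


def read_fasta(path: str | Path, aligned: bool = True,
               labels: Mapping[str, str] | None = None) -> Alignment:
    """Read a FASTA file, preserving order and uppercasing residues.

    In aligned mode all records must have equal length; duplicate headers and
    characters outside the amino-acid/gap alphabet raise :class:`FastaFormatError`.
    """
    ids: list[str] = []
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FastaFormatError(f"duplicate sequence ids: [{rec.id!r}]")
        ids.append(rec.id)
        rows[rec.id] = str(rec.seq).upper()
    if not ids:
        raise FastaFormatError(f"no FASTA records in {path}")
    return Alignment(ids=ids, rows=rows, labels=dict(labels or {}), aligned=aligned)


def write_fasta(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(alignment.rows[i]), id=i, description="") for i in alignment.ids
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Bio.SeqIO wraps at its own default; width kept for API stability


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sequence metadata TSV (columns: phage, cluster, location)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"phage", "cluster", "location"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    return df


def define_site_sets(alignment: Alignment, elements: Sequence) -> list[SiteSet]:
    """Partition the alignment columns into one site set per insertion element
    plus the complementary "extein" set.

    ``elements`` provides ``name`` and a half-open ``block`` attribute (or
    ``(name, start, end)`` tuples).  The returned sets are pairwise disjoint
    and their union is every column of the alignment.
    """
    L = alignment.n_columns
    parsed: list[tuple[str, int, int]] = []
    for el in elements:
        if hasattr(el, "block"):
            name, (start, end) = el.name, el.block
        else:
            name, start, end = el
        if not (0 <= start < end <= L):
            raise ValueError(f"element {name!r} block [{start},{end}) outside [0,{L})")
        parsed.append((name, start, end))
    parsed.sort(key=lambda t: t[1])
    for (n1, _, e1), (n2, s2, _) in zip(parsed, parsed[1:]):
        if s2 < e1:
            raise ValueError(f"elements {n1!r} and {n2!r} overlap")
    covered: set[int] = set()
    out: list[SiteSet] = []
    for name, start, end in parsed:
        out.append(SiteSet(name, tuple(range(start, end))))
        covered.update(range(start, end))
    extein_cols = tuple(c for c in range(L) if c not in covered)
    return [SiteSet("extein", extein_cols)] + out


def extract_partition(alignment: Alignment, site_set: SiteSet,
                      carriers_only: bool = False, min_span: float = 0.5) -> Partition:
    """Restrict an alignment to a site set's columns.

    With ``carriers_only`` rows whose non-gap occupancy over those columns is
    below ``min_span`` are dropped (their ids are recorded on the result).
    """
    L = alignment.n_columns
    if site_set.columns and site_set.columns[-1] >= L:
        raise ValueError(f"site set {site_set.name!r} exceeds alignment width {L}")
    if not site_set.columns:
        raise EmptyPartitionError(f"site set {site_set.name!r} is empty")
    cols = site_set.columns
    sub_rows = {i: "".join(alignment.rows[i][c] for c in cols) for i in alignment.ids}
    dropped: list[str] = []
    ids = list(alignment.ids)
    if carriers_only:
        kept = []
        for i in ids:
            row = sub_rows[i]
            occ = 1.0 - row.count(GAP) / len(row)
            if occ >= min_span:
                kept.append(i)
            else:
                dropped.append(i)
        ids = kept
        if not ids:
            raise EmptyPartitionError(
                f"no rows span >= {min_span:.2f} of site set {site_set.name!r}"
            )
    sub = Alignment(
        ids=ids,
        rows={i: sub_rows[i] for i in ids},
        labels={i: alignment.labels[i] for i in ids if i in alignment.labels},
    )
    return Partition(site_set.name, sub, site_set, carriers_only, tuple(dropped))


def column_residue_map(alignment: Alignment, sid: str) -> dict[int, int]:
    """Map each non-gap column of a row to its 0-based ungapped residue index."""
    if sid not in alignment.rows:
        raise KeyError(sid)
    out: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(alignment.rows[sid]):
        if ch != GAP:
            out[col] = k
            k += 1
    return out


def write_site_sets(site_sets: Sequence[SiteSet], path: str | Path) -> None:
    """Serialize site sets as a TSV of contiguous blocks: name, start, end."""
    recs = [
        {"name": ss.name, "start": s, "end": e}
        for ss in site_sets
        for s, e in ss.blocks()
    ]
    pd.DataFrame(recs, columns=["name", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_site_sets(path: str | Path) -> list[SiteSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("name", sort=False):
        out.append(SiteSet.from_blocks(str(name), zip(grp["start"], grp["end"])))
    return out


def write_carrier_report(elements: Sequence, path: str | Path) -> None:
    """JSON report of detected elements: block, carriers, occupancy."""
    payload = [
        {
            "name": el.name,
            "block": list(el.block),
            "carriers": sorted(el.carriers),
            "occupancy": el.occupancy,
            "flank_occupancy": el.flank_occupancy,
        }
        for el in elements
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
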