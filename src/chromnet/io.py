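"""Readers and writers for on-disk artifacts.

All genomic coordinates are 0-based half-open (BED convention):
an interval [a, b) covers bases a .. b-1, so [a, b) and [b, c) do not
overlap. Fragments are restriction fragments (e.g. HindIII fragments)
carried as BED with a 4th column holding the fragment id and an optional
5th column holding a mappability flag. Interaction calls arrive as a
tab-delimited table of pre-scored fragment pairs; this package never
recomputes interaction significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Fragment",
    "FragmentSet",
    "InteractionRecord",
    "FeatureTrack",
    "SignalTrack",
    "ParseError",
    "read_fragments",
    "write_fragments",
    "read_interactions",
    "write_interactions",
    "read_features",
    "write_features",
    "read_signal",
    "write_signal",
    "read_partition",
    "write_partition",
    "write_clique_table",
    "read_clique_table",
    "write_edgelist",
]


class ParseError(ValueError):
    """Malformed record in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: the genomic unit used as a network node."""

    id: str
    chrom: str
    start: int
    end: int
    mappable: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """An ordered collection of fragments with unique ids.

    Iteration yields fragments in insertion order; lookup is by id.
    """

    def __init__(self, fragments: Iterable[Fragment] = ()):
        self._by_id: dict[str, Fragment] = {}
        for frag in fragments:
            self.add(frag)

    def add(self, frag: Fragment) -> None:
        if frag.id in self._by_id:
            raise ValueError(f"duplicate fragment id: {frag.id!r}")
        self._by_id[frag.id] = frag

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self._by_id.values())

    def __contains__(self, frag_id: str) -> bool:
        return frag_id in self._by_id

    def __getitem__(self, frag_id: str) -> Fragment:
        return self._by_id[frag_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return list(self) == list(other)

    def ids(self) -> list[str]:
        return list(self._by_id)

    def chrom_of(self, frag_id: str) -> str:
        return self._by_id[frag_id].chrom

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for frag in self:
            seen.setdefault(frag.chrom, None)
        return list(seen)


@dataclass(frozen=True)
class InteractionRecord:
    """A scored, unordered fragment pair — an edge candidate.

    ``cls`` is "intra" when both fragments lie on the same chromosome and
    "inter" otherwise. The pair is stored in sorted id order so that
    (a, b) and (b, a) compare equal.
    """

    frag_a: str
    frag_b: str
    fdr: float
    cls: str

    def __post_init__(self):
        if self.frag_a == self.frag_b:
            raise ValueError(f"self-interaction rejected: {self.frag_a!r}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")
        if self.cls not in ("inter", "intra"):
            raise ValueError(f"unknown interaction class {self.cls!r}")
        if self.frag_a > self.frag_b:
            a, b = self.frag_a, self.frag_b
            object.__setattr__(self, "frag_a", b)
            object.__setattr__(self, "frag_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.frag_a, self.frag_b)


@dataclass
class FeatureTrack:
    """A binary annotation: named set of genomic intervals (BED)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"feature track {self.name!r}: interval {chrom}:{start}-{end} "
                    "has start >= end"
                )


@dataclass
class SignalTrack:
    """A continuous signal: named intervals with a real value (bedGraph)."""

    name: str
    intervals: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end, value in self.intervals:
            if start >= end:
                raise ValueError(
                    f"signal track {self.name!r}: interval {chrom}:{start}-{end} "
                    "has start >= end"
                )
            if not math.isfinite(value):
                raise ValueError(
                    f"signal track {self.name!r}: non-finite value at "
                    f"{chrom}:{start}-{end}"
                )


def _data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_fragments(path, drop_unmappable: bool = True) -> FragmentSet:
    """Read fragments from BED (chrom, start, end, id[, mappable]).

    A missing mappability column defaults to mappable. Unmappable fragments
    are dropped at read time unless ``drop_unmappable`` is False, mirroring
    the rule that only fragments passing the mappability criteria enter the
    networks.
    """
    frags = FragmentSet()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(path, lineno, f"expected >=4 BED columns, got {len(cols)}")
        chrom, start_s, end_s, frag_id = cols[0], cols[1], cols[2], cols[3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        mappable = True
        if len(cols) >= 5:
            flag = cols[4].strip().lower()
            if flag in _TRUE:
                mappable = True
            elif flag in _FALSE:
                mappable = False
            else:
                raise ParseError(path, lineno, f"unrecognized mappability flag {cols[4]!r}")
        if start >= end:
            raise ParseError(path, lineno, f"start ({start}) must be < end ({end})")
        if drop_unmappable and not mappable:
            continue
        try:
            frags.add(Fragment(frag_id, chrom, start, end, mappable))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    return frags


def write_fragments(frags: FragmentSet, path) -> None:
    with open(path, "w") as handle:
        for frag in frags:
            handle.write(
                f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.id}\t"
                f"{1 if frag.mappable else 0}\n"
            )


def read_interactions(path, fragments: FragmentSet) -> list[InteractionRecord]:
    """Read scored fragment pairs from TSV (frag_a, frag_b, fdr header).

    The inter/intra class is derived from the fragments' chromosomes.
    Unordered duplicates collapse to a single record keeping the minimum
    FDR (the most permissive score a pair achieved).
    """
    best: dict[tuple[str, str], InteractionRecord] = {}
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if header is None:
            header = [c.strip().lower() for c in cols]
            required = {"frag_a", "frag_b", "fdr"}
            if not required.issubset(header):
                raise ParseError(
                    path, lineno, f"header must contain frag_a, frag_b, fdr; got {cols}"
                )
            idx = {name: header.index(name) for name in required}
            continue
        try:
            a, b = cols[idx["frag_a"]], cols[idx["frag_b"]]
            fdr = float(cols[idx["fdr"]])
        except (IndexError, ValueError):
            raise ParseError(path, lineno, f"malformed interaction row: {line!r}")
        for frag_id in (a, b):
            if frag_id not in fragments:
                raise ParseError(path, lineno, f"unknown fragment id {frag_id!r}")
        cls = "intra" if fragments.chrom_of(a) == fragments.chrom_of(b) else "inter"
        try:
            rec = InteractionRecord(a, b, fdr, cls)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        prev = best.get(rec.pair)
        if prev is None or rec.fdr < prev.fdr:
            best[rec.pair] = rec
    return list(best.values())


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    with open(path, "w") as handle:
        handle.write("frag_a\tfrag_b\tfdr\n")
        for rec in records:
            handle.write(f"{rec.frag_a}\t{rec.frag_b}\t{rec.fdr:.10g}\n")


def read_features(path, name: str | None = None) -> FeatureTrack:
    """Read a binary feature track from BED. An empty file is an empty track."""
    if name is None:
        name = Path(path).stem
    intervals = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(path, lineno, f"expected >=3 BED columns, got {len(cols)}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates")
        if start >= end:
            raise ParseError(path, lineno, f"start ({start}) must be < end ({end})")
        intervals.append((cols[0], start, end))
    return FeatureTrack(name, intervals)


def write_features(track: FeatureTrack, path) -> None:
    with open(path, "w") as handle:
        for chrom, start, end in track.intervals:
            handle.write(f"{chrom}\t{start}\t{end}\n")


def read_signal(path, name: str | None = None) -> SignalTrack:
    """Read a continuous track from bedGraph (chrom, start, end, value)."""
    if name is None:
        name = Path(path).stem
    intervals = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(path, lineno, f"expected 4 bedGraph columns, got {len(cols)}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates")
        try:
            value = float(cols[3])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric signal value {cols[3]!r}")
        if not math.isfinite(value):
            raise ParseError(path, lineno, f"non-finite signal value {cols[3]!r}")
        if start >= end:
            raise ParseError(path, lineno, f"start ({start}) must be < end ({end})")
        intervals.append((cols[0], start, end, value))
    return SignalTrack(name, intervals)


def write_signal(track: SignalTrack, path) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, value in track.intervals:
            handle.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def write_partition(levels: list[Mapping[str, int]], path) -> None:
    """Write a hierarchical partition as TSV: fragment, level_0 .. level_k.

    ``levels`` is ordered finest (level 0) to final solution (top level);
    every node must be assigned at every level.
    """
    if not levels:
        raise ValueError("no partition levels to write")
    nodes = sorted(levels[0])
    for i, level in enumerate(levels):
        if set(level) != set(nodes):
            raise ValueError(f"level {i} does not cover the same node set as level 0")
    with open(path, "w") as handle:
        handle.write("fragment\t" + "\t".join(f"level_{i}" for i in range(len(levels))) + "\n")
        for node in nodes:
            handle.write(node + "\t" + "\t".join(str(level[node]) for level in levels) + "\n")


def read_partition(path) -> list[dict[str, int]]:
    levels: list[dict[str, int]] | None = None
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if levels is None:
            if cols[0] != "fragment":
                raise ParseError(path, lineno, "expected header starting with 'fragment'")
            levels = [{} for _ in cols[1:]]
            continue
        if len(cols) != len(levels) + 1:
            raise ParseError(path, lineno, "column count does not match header")
        try:
            for level, value in zip(levels, cols[1:]):
                level[cols[0]] = int(value)
        except ValueError:
            raise ParseError(path, lineno, "non-integer community id")
    if levels is None:
        raise ParseError(path, 1, "empty partition file")
    return levels


def write_clique_table(
    sizes: Mapping[str, int], path, signal: Mapping[str, float] | None = None
) -> None:
    """Write per-fragment maximum clique sizes (optionally with a signal column)."""
    with open(path, "w") as handle:
        if signal is None:
            handle.write("fragment\tmax_clique_size\n")
            for node in sorted(sizes):
                handle.write(f"{node}\t{sizes[node]}\n")
        else:
            handle.write("fragment\tmax_clique_size\tsignal\n")
            for node in sorted(sizes):
                val = signal.get(node)
                out = "NA" if val is None or (isinstance(val, float) and math.isnan(val)) else f"{val:.10g}"
                handle.write(f"{node}\t{sizes[node]}\t{out}\n")


def read_clique_table(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    saw_header = False
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if not saw_header:
            if cols[0] != "fragment":
                raise ParseError(path, lineno, "expected header starting with 'fragment'")
            saw_header = True
            continue
        try:
            sizes[cols[0]] = int(cols[1])
        except (IndexError, ValueError):
            raise ParseError(path, lineno, f"malformed clique-table row: {line!r}")
    return sizes


def write_edgelist(edges: Iterable[tuple[str, str]], path) -> None:
    """Plain two-column edge list for external graph viewers."""
    with open(path, "w") as handle:
        for u, v in edges:
            handle.write(f"{u}\t{v}\n")
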