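"""Readers and writers for the external file dialects the pipeline touches.

Three inputs drive everything downstream: pair lists (two-column TSV of
protein identifiers, used for positives, curated non-interactions, and
candidate sets), GO annotations in GAF 2.x, and sequence-search output in
BLAST ``outfmt 6`` tabular form. Protein identifiers are treated as opaque
strings throughout; mapping between accession schemes is the caller's
responsibility.

Pairs are unordered: ``(a, b)`` and ``(b, a)`` denote the same pair and are
stored canonically with ``first <= second`` lexicographically. This prevents
mirrored duplicates from leaking between training and test sets.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger("neglog")

ProteinPair = tuple[str, str]

#: GO aspects as they appear in GAF column 9.
GO_ASPECTS = frozenset({"C", "F", "P"})


class PairListParseError(ValueError):
    """A pair-list line could not be parsed; the message names the line."""


def canonical_pair(a: str, b: str) -> ProteinPair:
    """Return the canonical (lexicographically ordered) form of a pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PairList:
    """An ordered, deduplicated collection of canonical protein pairs.

    Parameters
    ----------
    pairs:
        Canonical pairs, in first-seen order.
    label:
        Optional class tag (+1 or -1) applying to the whole list.
    source:
        Free-text provenance string (file path, generator description, ...).
    """

    pairs: list[ProteinPair] = field(default_factory=list)
    label: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (-1, +1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")
        seen: set[ProteinPair] = set()
        out: list[ProteinPair] = []
        for a, b in self.pairs:
            p = canonical_pair(a, b)
            if p not in seen:
                seen.add(p)
                out.append(p)
        self.pairs = out

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ProteinPair]:
        return iter(self.pairs)

    def __contains__(self, pair: ProteinPair) -> bool:
        return canonical_pair(*pair) in self.pair_set

    @property
    def pair_set(self) -> set[ProteinPair]:
        return set(self.pairs)

    def proteins(self) -> set[str]:
        """All distinct proteins occurring in the list."""
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_pair_list(
    path: str | Path,
    label: int | None = None,
    *,
    allow_self: bool = False,
) -> PairList:
    """Read a two(+)-column TSV of protein pairs.

    Tab- or whitespace-separated; lines starting with ``#`` are comments;
    columns beyond the second are ignored. Mirror duplicates collapse to one
    canonical pair. Self-pairs ``(a, a)`` are dropped with a warning unless
    ``allow_self`` is set (homodimers are real, but Negatome-style pair
    semantics exclude them by default).
    """
    pairs: list[ProteinPair] = []
    n_self = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise PairListParseError(
                    f"{path}: line {lineno}: expected >=2 columns, got {len(cols)}"
                )
            a, b = cols[0].strip(), cols[1].strip()
            if a == b and not allow_self:
                n_self += 1
                continue
            pairs.append(canonical_pair(a, b))
    pl = PairList(pairs=pairs, label=label, source=str(path))
    n_dup = len(pairs) - len(pl)
    if n_self:
        logger.warning("%s: dropped %d self-pair(s)", path, n_self)
    if n_dup:
        logger.info("%s: collapsed %d duplicate pair(s)", path, n_dup)
    return pl


def write_pair_list(pl: PairList | Iterable[ProteinPair], path: str | Path) -> Path:
    """Write canonical pairs as two-column TSV (one pair per line)."""
    path = Path(path)
    pairs = pl.pairs if isinstance(pl, PairList) else [canonical_pair(*p) for p in pl]
    with open(path, "wt") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
    return path


def read_gaf(
    path: str | Path,
    aspects: Iterable[str] = ("C", "F", "P"),
) -> dict[str, set[str]]:
    """Read a GAF 2.x gene-association file into protein -> GO-term sets.

    Only annotations in the requested ``aspects`` (subset of {C, F, P},
    GAF column 9) are kept. Rows whose qualifier (column 4) carries ``NOT``
    assert *absence* of function and are excluded. Malformed rows are
    skipped with a warning; a file with zero usable rows is an error.

    The protein identifier is GAF column 2 (DB Object ID).
    """
    aspects = set(aspects)
    if not aspects <= GO_ASPECTS:
        raise ValueError(f"aspects must be a subset of {{C,F,P}}, got {aspects}")
    store: dict[str, set[str]] = {}
    n_rows = 0
    n_bad = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                n_bad += 1
                logger.warning("%s: line %d: <9 GAF columns, skipped", path, lineno)
                continue
            protein, qualifier, term, aspect = cols[1], cols[3], cols[4], cols[8]
            if not protein or not term.startswith("GO:") or aspect not in GO_ASPECTS:
                n_bad += 1
                logger.warning("%s: line %d: malformed GAF row, skipped", path, lineno)
                continue
            n_rows += 1
            if "NOT" in qualifier.split("|"):
                continue
            if aspect not in aspects:
                # Still registers the protein so "annotated but filtered"
                # differs from "never seen" only by presence of the key.
                store.setdefault(protein, set())
                continue
            store.setdefault(protein, set()).add(term)
    if n_rows == 0:
        raise ValueError(f"{path}: no usable GAF rows")
    return store


def read_blast_tabular(
    path: str | Path,
    evalue_max: float = 1e-20,
) -> dict[str, dict[str, float]]:
    """Read BLAST/PSI-BLAST ``outfmt 6`` tabular output into a homolog map.

    Returns ``query -> {subject: evalue}`` keeping hits with
    ``evalue <= evalue_max`` (the homology cutoff; 1e-20 by default, the
    stringency at which hits are treated as paralogs/orthologs). Self-hits
    are removed; for repeated query/subject rows (multiple HSPs) the
    smallest E-value wins. Rows with an unparseable E-value are skipped
    with a warning. An empty file yields an empty map.
    """
    hits: dict[str, dict[str, float]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                logger.warning("%s: line %d: <12 columns, skipped", path, lineno)
                continue
            query, subject = cols[0], cols[1]
            try:
                evalue = float(cols[10])
            except ValueError:
                logger.warning("%s: line %d: bad E-value %r, skipped", path, lineno, cols[10])
                continue
            if query == subject or evalue > evalue_max:
                continue
            prev = hits.setdefault(query, {}).get(subject)
            if prev is None or evalue < prev:
                hits[query][subject] = evalue
    return hits
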