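"""The paralog/ortholog relation used for negative-pair expansion and
homolog-instance features.

A :class:`HomologyMap` is a thresholded neighbor relation built from
sequence-search hits: protein -> {homolog: E-value}, keeping only hits at
or below the construction-time E-value ceiling. BLAST hit lists are
directional, but paralogy is a symmetric concept, so maps are usually
symmetrized (keeping the more significant E-value per edge) before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import read_blast_tabular

DEFAULT_EVALUE_MAX = 1e-20


@dataclass
class HomologyMap:
    """Protein -> homologous-protein relation with E-values.

    Invariants: no protein is its own neighbor; all stored E-values are
    at or below ``threshold``.
    """

    neighbors: dict[str, dict[str, float]] = field(default_factory=dict)
    threshold: float = DEFAULT_EVALUE_MAX

    def __post_init__(self) -> None:
        for prot, hits in self.neighbors.items():
            if prot in hits:
                raise ValueError(f"{prot} listed as its own homolog")
            bad = [e for e in hits.values() if e > self.threshold]
            if bad:
                raise ValueError(
                    f"{prot}: E-value(s) above threshold {self.threshold:g}: {bad}"
                )

    @classmethod
    def from_blast_tabular(
        cls, path: str | Path, evalue_max: float = DEFAULT_EVALUE_MAX
    ) -> "HomologyMap":
        return cls(neighbors=read_blast_tabular(path, evalue_max), threshold=evalue_max)

    def homologs_of(self, protein: str) -> set[str]:
        """Neighbor set of ``protein``; empty for unknown proteins."""
        return set(self.neighbors.get(protein, ()))

    def evalue(self, a: str, b: str) -> float | None:
        return self.neighbors.get(a, {}).get(b)

    def symmetrize(self) -> "HomologyMap":
        """Return a symmetric closure: b in N(a) implies a in N(b).

        Where both directions exist with different E-values the smaller
        (more significant) one is kept on both. Idempotent; neighbor sets
        only grow.
        """
        merged: dict[str, dict[str, float]] = {
            p: dict(hits) for p, hits in self.neighbors.items()
        }
        for a, hits in self.neighbors.items():
            for b, e in hits.items():
                for x, y in ((a, b), (b, a)):
                    prev = merged.setdefault(x, {}).get(y)
                    if prev is None or e < prev:
                        merged[x][y] = e
        return HomologyMap(neighbors=merged, threshold=self.threshold)

    def to_tsv(self, path: str | Path) -> Path:
        """Serialize as 3-column TSV (protein, homolog, evalue)."""
        path = Path(path)
        with open(path, "wt") as fh:
            for a in sorted(self.neighbors):
                for b in sorted(self.neighbors[a]):
                    fh.write(f"{a}\t{b}\t{self.neighbors[a][b]:g}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = DEFAULT_EVALUE_MAX) -> "HomologyMap":
        neighbors: dict[str, dict[str, float]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b, e = line.rstrip("\n").split("\t")
                neighbors.setdefault(a, {})[b] = float(e)
        return cls(neighbors=neighbors, threshold=threshold)
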