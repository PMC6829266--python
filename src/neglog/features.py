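"""GO-term feature encoding of protein pairs.

Each protein ``i`` carries two GO-term sets: its own annotations (the
*target* set ``ST_i``) and the union of its homologs' annotations (the
*homolog* set ``SH_i``), the latter transferring annotation knowledge to
sparsely annotated proteins. The vocabulary ``S`` is the union of both
sets over all proteins occurring in the training pairs; terms outside
``S`` are discarded at encoding time.

A pair ``(i1, i2)`` becomes two fixed-length vectors over ``S``, one per
instance kind, with the component for term ``g`` equal to

    2  if both proteins carry g,
    1  if exactly one does,
    0  if neither does,

so a component records co-occurrence versus individual presence of a
term within the pair. The representation is deliberately flat: no DAG
propagation, ancestors or semantic similarity, which keeps inter-feature
correlation low. Vectors are materialized sparsely (most components are
zero at genome scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .homology import HomologyMap
from .io_formats import PairList, ProteinPair

InstanceKind = Literal["target", "homolog"]


@dataclass
class AnnotationStore:
    """Per-protein GO-term sets, split into target and homolog views.

    Unknown proteins have empty sets (never an error: test pairs may
    involve proteins unseen in training or in the annotation source).
    """

    target_terms: dict[str, set[str]] = field(default_factory=dict)
    homolog_terms: dict[str, set[str]] = field(default_factory=dict)

    def terms(self, protein: str, kind: InstanceKind) -> set[str]:
        source = self.target_terms if kind == "target" else self.homolog_terms
        return source.get(protein, set())


def build_homolog_terms(store: AnnotationStore, hmap: HomologyMap) -> AnnotationStore:
    """Fill the homolog view: SH(i) = union of ST(h) over homologs h of i.

    Returns a new store sharing the target view. Every protein that is
    annotated or appears in the homology map gets an entry.
    """
    homolog_terms: dict[str, set[str]] = {}
    proteins = set(store.target_terms) | set(hmap.neighbors)
    for prot in proteins:
        acc: set[str] = set()
        for h in hmap.homologs_of(prot):
            acc |= store.target_terms.get(h, set())
        homolog_terms[prot] = acc
    return AnnotationStore(target_terms=store.target_terms, homolog_terms=homolog_terms)


@dataclass
class Vocabulary:
    """Deterministically ordered GO-term vocabulary with term -> column index."""

    terms: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.terms = sorted(self.terms)
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text("".join(t + "\n" for t in self.terms))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        terms = [t for t in Path(path).read_text().splitlines() if t]
        return cls(terms=terms)


def build_vocabulary(training: PairList | Iterable[ProteinPair], store: AnnotationStore) -> Vocabulary:
    """Union of target and homolog term sets over all training-pair proteins."""
    union: set[str] = set()
    n_pairs = 0
    for a, b in training:
        n_pairs += 1
        for prot in (a, b):
            union |= store.terms(prot, "target")
            union |= store.terms(prot, "homolog")
    if n_pairs == 0 or not union:
        raise ValueError("empty GO vocabulary: no annotated training pairs")
    return Vocabulary(terms=sorted(union))


@dataclass
class PairFeatures:
    """The two {0,1,2} feature vectors of one pair (1 x |S| sparse rows)."""

    vt: sp.csr_matrix
    vh: sp.csr_matrix


def _indicator_rows(
    proteins: Sequence[str], store: AnnotationStore, vocab: Vocabulary, kind: InstanceKind
) -> sp.csr_matrix:
    """0/1 membership matrix: row per protein, column per vocabulary term."""
    indptr = [0]
    indices: list[int] = []
    for prot in proteins:
        cols = sorted(vocab.index[t] for t in store.terms(prot, kind) if t in vocab)
        indices.extend(cols)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.int8)
    return sp.csr_matrix(
        (data, indices, indptr), shape=(len(proteins), len(vocab)), dtype=np.int8
    )


def encode_pairs(
    pairs: PairList | Sequence[ProteinPair], store: AnnotationStore, vocab: Vocabulary
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Encode many pairs at once; returns (target, homolog) CSR matrices.

    Row k encodes pair k; summing the two proteins' 0/1 membership rows
    yields exactly the {0,1,2} co-occurrence coding.
    """
    pairs = list(pairs)
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    firsts = [a for a, _ in pairs]
    seconds = [b for _, b in pairs]
    mats = []
    for kind in ("target", "homolog"):
        m = _indicator_rows(firsts, store, vocab, kind) + _indicator_rows(
            seconds, store, vocab, kind
        )
        mats.append(m.astype(np.float64).tocsr())
    return mats[0], mats[1]


def encode_pair(pair: ProteinPair, store: AnnotationStore, vocab: Vocabulary) -> PairFeatures:
    """Encode a single pair into its target and homolog instance vectors."""
    vt, vh = encode_pairs([pair], store, vocab)
    return PairFeatures(vt=vt, vh=vh)


def write_sparse_triplets(matrix: sp.spmatrix, path: str | Path) -> Path:
    """Write a feature matrix as text triplets: row, col, value (0-based)."""
    coo = sp.coo_matrix(matrix)
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write(f"# shape\t{coo.shape[0]}\t{coo.shape[1]}\n")
        order = np.lexsort((coo.col, coo.row))
        for i in order:
            fh.write(f"{coo.row[i]}\t{coo.col[i]}\t{int(coo.data[i])}\n")
    return path


def read_sparse_triplets(path: str | Path) -> sp.csr_matrix:
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    shape = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# shape"):
                _, r, c = line.rstrip("\n").split("\t")
                shape = (int(r), int(c))
                continue
            if not line.strip() or line.startswith("#"):
                continue
            r, c, v = line.split("\t")
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    if shape is None:
        raise ValueError(f"{path}: missing '# shape' header")
    return sp.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()
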