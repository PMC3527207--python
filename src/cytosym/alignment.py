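"""Gap-free partitioned alignments built from reference-anchored consensus sequences.

Consensus sequences are all the same length as their reference, so a multiple
alignment is just a character matrix; the only filtering step is dropping
every column in which any strain carries an N (fully ambiguous call or
deletion relative to the reference).  Surviving columns keep their 1-based
reference coordinate and a site-class annotation (codon position / RNA /
intergenic), which downstream rate models partition on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .substitution import ALPHABET, decode_sequence, encode_sequence

SITE_CLASSES = ("codon1", "codon2", "codon3", "ncRNA", "noncoding")


@dataclass
class PartitionedAlignment:
    """Ungapped character matrix with per-column metadata.

    Attributes
    ----------
    ids : strain identifiers, one per row.
    matrix : int8 array (n_strains, n_columns), codes 0..3 for A,C,G,T.
    site_class : per-column class label.
    coords : per-column 1-based coordinate on the source reference.
    reference_id : name of the source reference sequence.
    """

    ids: list[str]
    matrix: np.ndarray
    site_class: np.ndarray
    coords: np.ndarray
    reference_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.site_class = np.asarray(self.site_class, dtype=object)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        n, L = self.matrix.shape
        if len(self.ids) != n:
            raise ValueError("row count does not match number of ids")
        if self.site_class.shape != (L,) or self.coords.shape != (L,):
            raise ValueError("per-column metadata length mismatch")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("alignment must be gap- and N-free")
        if L > 1 and np.any(np.diff(self.coords) <= 0):
            raise ValueError("reference coordinates must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return decode_sequence(self.matrix[i])

    def subset_columns(self, mask) -> "PartitionedAlignment":
        return replace(
            self,
            matrix=self.matrix[:, mask],
            site_class=self.site_class[mask],
            coords=self.coords[mask],
        )

    def subset_rows(self, ids: list[str]) -> "PartitionedAlignment":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return replace(self, ids=list(ids), matrix=self.matrix[rows])

    def base_frequencies(self) -> np.ndarray:
        counts = np.bincount(self.matrix.ravel(), minlength=4).astype(float)
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        return counts / total

    def variable_columns(self) -> np.ndarray:
        """Boolean mask of polymorphic columns."""
        if self.n_columns == 0:
            return np.zeros(0, dtype=bool)
        return (self.matrix != self.matrix[0]).any(axis=0)


def build_ungapped_alignment(
    consensus: dict[str, str],
    annotation: np.ndarray | list[str],
    reference_id: str = "",
) -> PartitionedAlignment:
    """Stack same-length consensus sequences and drop every column with an N.

    Parameters
    ----------
    consensus : mapping strain_id -> consensus string (A/C/G/T/N, one char per
        reference position).  Deletions must already be coded as N.
    annotation : site-class label per reference position.
    """
    ids = list(consensus)
    if not ids:
        raise ValueError("no sequences supplied")
    lengths = {len(s) for s in consensus.values()}
    if len(lengths) != 1:
        raise ValueError("consensus sequences differ in length")
    (L,) = lengths
    annotation = np.asarray(annotation, dtype=object)
    if annotation.shape != (L,):
        raise ValueError("annotation length does not match sequence length")
    matrix = np.vstack([encode_sequence(consensus[s]) for s in ids])
    keep = (matrix >= 0).all(axis=0)
    return PartitionedAlignment(
        ids=ids,
        matrix=matrix[:, keep],
        site_class=annotation[keep],
        coords=np.flatnonzero(keep) + 1,
        reference_id=reference_id,
    )


def concatenate(alignments: list[PartitionedAlignment],
                class_prefixes: list[str] | None = None) -> PartitionedAlignment:
    """Concatenate alignments over the same strain set (rows matched by id).

    ``class_prefixes`` optionally prefixes each alignment's site classes
    (e.g. ``"mt:"``, ``"wol:"``) so partitions from different genomes stay
    distinguishable after concatenation.  Coordinates are re-indexed to the
    concatenated alignment (1-based).
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    ids = alignments[0].ids
    mats, classes = [], []
    for k, aln in enumerate(alignments):
        a = aln if aln.ids == ids else aln.subset_rows(ids)
        mats.append(a.matrix)
        cls = a.site_class
        if class_prefixes is not None:
            cls = np.array([class_prefixes[k] + c for c in cls], dtype=object)
        classes.append(cls)
    matrix = np.hstack(mats)
    return PartitionedAlignment(
        ids=list(ids),
        matrix=matrix,
        site_class=np.concatenate(classes),
        coords=np.arange(1, matrix.shape[1] + 1),
        reference_id="concatenated",
    )


def variable_sites_table(aln: PartitionedAlignment):
    """Tidy table of polymorphic columns: reference coordinate, alignment
    coordinate (1-based position among the retained columns), site class and
    the alleles carried per strain."""
    import pandas as pd

    mask = aln.variable_columns()
    cols = np.flatnonzero(mask)
    rows = []
    for aln_pos, c in enumerate(cols, start=0):
        alleles = "".join(ALPHABET[b] for b in aln.matrix[:, c])
        rows.append({
            "reference_id": aln.reference_id,
            "ref_coord": int(aln.coords[c]),
            "aln_coord": int(c + 1),
            "class": aln.site_class[c],
            "alleles": alleles,
        })
    return pd.DataFrame(rows, columns=["reference_id", "ref_coord",
                                       "aln_coord", "class", "alleles"])


def pairwise_distances(aln: PartitionedAlignment, model: str = "raw") -> np.ndarray:
    """Pairwise distance matrix under ``raw`` (p-distance) or ``JC`` correction.

    JC: d = -(3/4) ln(1 - (4/3) p); raises on saturation (p >= 0.75).
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    if aln.n_columns < 1:
        raise ValueError("alignment has no columns")
    X = aln.matrix
    n, L = X.shape
    # mismatch counts via one-hot matmul: matches = sum_b I[x=b] I[y=b]
    onehot = np.stack([(X == b) for b in range(4)], axis=-1).astype(np.float64)
    matches = np.einsum("ilb,jlb->ij", onehot, onehot)
    p = 1.0 - matches / L
    np.fill_diagonal(p, 0.0)
    if model == "raw":
        return p
    if model == "JC":
        if np.any(p >= 0.75 - 1e-12):
            raise ValueError("JC distance undefined: p-distance at or above 3/4")
        d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown distance model {model!r}")
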