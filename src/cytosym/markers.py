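"""Marker-level genotyping of *Wolbachia* and mtDNA lineages.

Three independent marker systems distinguish the wMel-like from the
wMelCS-like cytotypes:

* presence/absence of an IS5-family (ISWpi1) transposon at two diagnostic
  *Wolbachia* loci, called from reads spanning the insertion or empty-site
  junction (an alignment-free stand-in for BLAT-based flank mapping);
* two diagnostic mtDNA SNPs (positions 2160 and 2187 of the mtDNA
  reference): T/C marks wMelCS-type, C/T marks wMel-type cytoplasm;
* COI haplotypes matched against a reference table, with novel haplotypes
  numbered sequentially from 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .substitution import decode_sequence, encode_sequence

logger = logging.getLogger(__name__)

#: diagnostic loci, 1-based inclusive windows on the wMel reference AE017196
IS5_LOCI = {
    "WD0516_7": (507322, 509812),
    "WD1310": (1251363, 1252108),
}

#: COI gene window in mtDNA-local coordinates (1-based inclusive); derived
#: from the gene's chromosome-scaffold anchors relative to the mtDNA
#: reference start, length 555
COI_WINDOW = (1657, 2211)

MT_SNP_POSITIONS = (2160, 2187)

MIN_READ_LENGTH = 75  # junction typing needs reads longer than this


@dataclass
class IS5Call:
    locus: str
    window: tuple
    status: str                    # present | absent | indeterminate
    junction_reads: int            # reads supporting the insertion junction
    empty_reads: int = 0           # reads supporting the empty-site junction


@dataclass
class COIHaplotype:
    haplotype_id: int | None
    novel: bool
    ambiguous: bool = False


@dataclass
class JunctionReference:
    """One allelic state of a locus: the local haplotype sequence and the
    positions (1-based, boundary after that base) of its junctions."""

    sequence: str
    junctions: tuple

    def __post_init__(self):
        L = len(self.sequence)
        for j in self.junctions:
            if not 1 <= j < L:
                raise ValueError("junction outside the reference sequence")


def _read_support(reads, ref: str, junctions, overhang: int,
                  max_mismatch: int) -> int:
    """Count reads whose best gap-free placement on ``ref`` spans a junction
    with >= overhang matched bases on both sides (both orientations)."""
    ref_arr = encode_sequence(ref)
    L = ref_arr.size
    complement = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    count = 0
    for read in reads:
        hit = False
        for oriented in (read, "".join(complement[b] for b in reversed(read))):
            r = encode_sequence(oriented)
            RL = r.size
            if RL > L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, RL)
            mism = (windows != r).sum(axis=1)
            for o in np.flatnonzero(mism <= max_mismatch):
                # junction j = boundary between ref positions j and j+1
                for j in junctions:
                    if o + overhang <= j <= o + RL - overhang:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        if hit:
            count += 1
    return count


def detect_is5_presence(reads, locus: str,
                        insertion_ref: JunctionReference,
                        empty_ref: JunctionReference,
                        min_junction_reads: int = 3,
                        read_length: int | None = None,
                        overhang: int = 20,
                        max_mismatch: int = 2) -> IS5Call:
    """Call IS5 presence at one locus from junction-spanning reads.

    ``insertion_ref`` holds the haplotype carrying the element (junctions at
    both flank/element boundaries); ``empty_ref`` the element-free haplotype
    (one flank/flank junction).  A read supports a state when it places on
    that haplotype with at most ``max_mismatch`` mismatches and crosses a
    junction with at least ``overhang`` bases on each side.  Reads of length
    <= 75 bp cannot type the locus and give an indeterminate call, as do
    conflicting or absent signals.
    """
    if locus not in IS5_LOCI:
        raise ValueError(f"unknown locus {locus!r}")
    if insertion_ref is None or empty_ref is None:
        raise ValueError("both allelic reference haplotypes are required")
    window = IS5_LOCI[locus]
    reads = list(reads)
    rl = read_length if read_length is not None else (
        max((len(r) for r in reads), default=0))
    if rl <= MIN_READ_LENGTH:
        return IS5Call(locus, window, "indeterminate", 0, 0)
    ins = _read_support(reads, insertion_ref.sequence, insertion_ref.junctions,
                        overhang, max_mismatch)
    emp = _read_support(reads, empty_ref.sequence, empty_ref.junctions,
                        overhang, max_mismatch)
    if ins >= min_junction_reads and emp < min_junction_reads:
        status = "present"
    elif emp >= min_junction_reads and ins < min_junction_reads:
        status = "absent"
    else:
        status = "indeterminate"
    return IS5Call(locus, window, status, ins, emp)


def assign_is5_genotype(call_wd0516_7: IS5Call, call_wd1310: IS5Call) -> str:
    """Genotype from the two diagnostic calls.

    IS5 present at WD0516/7 and absent at WD1310 -> wMel-like; the converse
    -> wMelCS-like; absent at both -> wMel3; anything else indeterminate.
    """
    a, b = call_wd0516_7.status, call_wd1310.status
    table = {
        ("present", "absent"): "wMel-like",
        ("absent", "present"): "wMelCS-like",
        ("absent", "absent"): "wMel3",
    }
    return table.get((a, b), "indeterminate")


def classify_mt_snp_type(mt_consensus: str,
                         positions: tuple = MT_SNP_POSITIONS) -> str:
    """Type the cytoplasm from the two diagnostic mtDNA SNPs.

    (T, C) at the two positions -> wMelCS-type; (C, T) -> wMel-type;
    anything else (including N) -> unknown.
    """
    p1, p2 = positions
    if len(mt_consensus) < max(p1, p2):
        raise ValueError("consensus does not cover the diagnostic positions")
    pair = (mt_consensus[p1 - 1].upper(), mt_consensus[p2 - 1].upper())
    if pair == ("T", "C"):
        return "wMelCS-type"
    if pair == ("C", "T"):
        return "wMel-type"
    return "unknown"


def extract_coi(mt_consensus: str, window: tuple = COI_WINDOW) -> str:
    """COI gene subsequence (mtDNA-local 1-based inclusive window)."""
    start, end = window
    if len(mt_consensus) < end:
        raise ValueError("consensus shorter than the COI window")
    return mt_consensus[start - 1:end]


class HaplotypeTable:
    """Known haplotype sequences with sequential numbering of novel ones.

    Matching ignores positions that are N in the query; a query compatible
    with more than one table entry is ambiguous and gets no id.  Novel
    haplotypes are appended to the working table (first novel id 20, then
    21, ...), so identical later queries reuse the same id.  Assignment must
    be run in a fixed, documented strain order to be reproducible.
    """

    def __init__(self, known: dict[int, str], first_new_id: int = 20):
        lengths = {len(s) for s in known.values()}
        if len(lengths) > 1:
            raise ValueError("haplotype table sequences differ in length")
        self.table = {int(k): v.upper() for k, v in known.items()}
        self.next_new_id = max([first_new_id] +
                               [k + 1 for k in self.table
                                if k >= first_new_id])

    def assign(self, query: str) -> COIHaplotype:
        if self.table:
            (L,) = {len(s) for s in self.table.values()}
            if len(query) != L:
                raise ValueError("query length does not match the table")
        q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
        informative = q != ord("N")
        matches = []
        for hid, seq in self.table.items():
            s = np.frombuffer(seq.encode(), dtype=np.uint8)
            if np.array_equal(q[informative], s[informative]):
                matches.append(hid)
        if len(matches) == 1:
            return COIHaplotype(matches[0], novel=False)
        if len(matches) > 1:
            logger.warning("query matches several haplotypes after N-masking: %s",
                           matches)
            return COIHaplotype(None, novel=False, ambiguous=True)
        new_id = self.next_new_id
        self.table[new_id] = query.upper()
        self.next_new_id += 1
        return COIHaplotype(new_id, novel=True)


def assign_coi_haplotype(coi_sequence: str, table: HaplotypeTable) -> COIHaplotype:
    """Assign one COI sequence against (and possibly extending) the table."""
    return table.assign(coi_sequence)


# ---------------------------------------------------------------------------
# read simulation (oracle support + demos)
# ---------------------------------------------------------------------------

def simulate_reads(sequence: str, depth: float, read_length: int,
                   error_rate: float, seed: int) -> list[str]:
    """Uniform single-end reads from one haplotype with per-base errors."""
    rng = np.random.default_rng(seed)
    codes = encode_sequence(sequence)
    L = codes.size
    if read_length > L:
        raise ValueError("reads longer than the template")
    n_reads = int(round(depth * L / read_length))
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    reads = []
    for s in starts:
        r = codes[s:s + read_length].copy()
        errs = np.flatnonzero(rng.random(read_length) < error_rate)
        for e in errs:
            r[e] = (r[e] + rng.integers(1, 4)) % 4
        reads.append(decode_sequence(r))
    return reads
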