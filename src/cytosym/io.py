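"""Readers and writers for the package's plain-text interchange formats.

All tables are TSV with 1-based inclusive coordinates; sequences are FASTA
(via Biopython); trees are Newick.  These functions round-trip the bundles
written by :func:`cytosym.synthetic.make_fixture_bundle` and also accept the
generic three-column ``reference position depth`` text produced by standard
genome-coverage utilities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import DepthProfile


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_depth_profiles(path) -> dict[tuple[str, str], DepthProfile]:
    """Bundle-format depth table (strain_id, reference_id, position, depth).

    Also accepts headerless three-column ``reference position depth`` text,
    in which case the strain id is the file stem.
    """
    path = Path(path)
    first = path.open().readline().split("\t")
    if first and first[0] == "strain_id":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["reference_id", "position", "depth"])
        df["strain_id"] = path.stem
    out = {}
    for (strain, ref), grp in df.groupby(["strain_id", "reference_id"],
                                         sort=True):
        grp = grp.sort_values("position")
        L = int(grp["position"].max())
        depths = np.zeros(L)
        depths[grp["position"].to_numpy(int) - 1] = grp["depth"].to_numpy(float)
        out[(strain, ref)] = DepthProfile(ref, depths)
    return out


def read_base_counts(path) -> dict[tuple[str, str], pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for (strain, ref), grp in df.groupby(["strain_id", "reference_id"],
                                         sort=True):
        out[(strain, ref)] = grp[["position", "A", "C", "G", "T", "del"]
                                 ].reset_index(drop=True)
    return out


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"strain_id", "population", "latitude", "longitude", "region",
                "ploidy"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def read_annotation(path) -> dict[str, np.ndarray]:
    """Per-reference site-class tracks from (reference_id, start, end, class)
    interval rows (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for ref, grp in df.groupby("reference_id", sort=True):
        L = int(grp["end"].max())
        track = np.full(L, "noncoding", dtype=object)
        for _, row in grp.iterrows():
            track[int(row["start"]) - 1:int(row["end"])] = row["class"]
        out[ref] = track
    return out


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_infection_calls(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
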