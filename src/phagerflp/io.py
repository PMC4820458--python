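"""File formats: FASTA genomes, enzyme/ladder/profile/lane tables.

FASTA goes through Biopython; tables are plain TSV/CSV via pandas.  All
readers validate into the package's domain types and raise ``ValueError``
with the offending record/offset on malformed input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import DigestProfile, GenomeSequence, RestrictionEnzyme
from .fingerprint import BandProfile, DistanceMatrix
from .gel import GelLane, SizeLadder, infer_sizes

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_enzymes",
    "read_ladder",
    "profiles_to_tsv",
    "read_band_profiles",
    "write_band_profiles",
    "lane_to_tsv",
    "matrix_to_csv",
]


def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeSequence]:
    """Read a multi-record FASTA into genomes, preserving record order.

    Sequences are uppercased; wrapped lines and CRLF endings are accepted.
    Empty files, empty records, duplicate ids and non-IUPAC characters are
    rejected with the record named in the error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (line 1)")
    genomes = []
    seen: set[str] = set()
    for idx, rec in enumerate(records, start=1):
        if not rec.id:
            raise ValueError(f"{path}: record {idx} has an empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        try:
            genomes.append(GenomeSequence(id=rec.id, seq=seq, topology=topology))  # type: ignore[arg-type]
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    return genomes


def write_fasta(genomes: Sequence[GenomeSequence], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_enzymes(path: str | Path) -> list[RestrictionEnzyme]:
    """Read enzyme definitions from a TSV: name, recognition, cut_offset."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "recognition", "cut_offset"}
    if not required.issubset(df.columns):
        raise ValueError(f"enzyme table needs columns {sorted(required)}")
    return [
        RestrictionEnzyme(str(r.name), str(r.recognition), int(r.cut_offset))
        for r in df.itertuples(index=False)
    ]


def read_ladder(path: str | Path) -> SizeLadder:
    """Read a size ladder TSV: size_bp, distance_mm."""
    df = pd.read_csv(path, sep="\t")
    if not {"size_bp", "distance_mm"}.issubset(df.columns):
        raise ValueError("ladder table needs columns size_bp, distance_mm")
    return SizeLadder(
        tuple(
            (float(r.size_bp), float(r.distance_mm))
            for r in df.itertuples(index=False)
        )
    )


def profiles_to_tsv(profiles: Sequence[DigestProfile], path: str | Path) -> None:
    """Write digest profiles: genome_id, enzyme, rank, length_bp, topology, uncut."""
    rows = [
        (p.genome_id, p.enzyme, rank, length, p.topology_used, p.uncut)
        for p in profiles
        for rank, length in enumerate(p.fragments, start=1)
    ]
    pd.DataFrame(
        rows,
        columns=["genome_id", "enzyme", "rank", "length_bp", "topology", "uncut"],
    ).to_csv(path, sep="\t", index=False)


def read_band_profiles(path: str | Path, source: str = "virtual_digest") -> list[BandProfile]:
    """Read band profiles from a TSV with columns id, size_bp (one band per row)."""
    df = pd.read_csv(path, sep="\t")
    if not {"id", "size_bp"}.issubset(df.columns):
        raise ValueError("profile table needs columns id, size_bp")
    return [
        BandProfile(
            id=str(pid),
            sizes=tuple(float(s) for s in group["size_bp"]),
            source=source,  # type: ignore[arg-type]
        )
        for pid, group in df.groupby("id", sort=False)
    ]


def write_band_profiles(profiles: Sequence[BandProfile], path: str | Path) -> None:
    rows = [(p.id, s) for p in profiles for s in p.sizes]
    pd.DataFrame(rows, columns=["id", "size_bp"]).to_csv(path, sep="\t", index=False)


def lane_to_tsv(lane: GelLane, model, path: str | Path) -> None:
    """Write a gel lane: lane_id, band_index, distance_mm, size_bp, multiplicity."""
    sizes = infer_sizes(lane, model)
    rows = [
        (lane.lane_id, i, round(b.distance_mm, 2), s, b.multiplicity)
        for i, (b, s) in enumerate(zip(lane.bands, sizes), start=1)
    ]
    pd.DataFrame(
        rows,
        columns=["lane_id", "band_index", "distance_mm", "size_bp", "multiplicity"],
    ).to_csv(path, sep="\t", index=False)


def matrix_to_csv(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square distance matrix as labelled CSV (full matrix for
    readability, lower triangle redundant)."""
    pd.DataFrame(dm.D, index=list(dm.labels), columns=list(dm.labels)).to_csv(
        path, float_format="%.4f"
    )
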