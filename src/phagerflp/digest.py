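"""Restriction-site mapping and fragment-length profiles.

Virtual digestion of a genome with a restriction endonuclease is the first
stage of RFLP typing: the positions of all recognition sites are located and
the lengths of the fragments between consecutive cuts become the genome's
restriction profile.  Both linear genomes (packaged phage DNA as extracted
from virions) and circular genomes (replicative forms, some database records)
are handled; circular digestion detects sites that span the sequence origin.

Coordinates are 0-based and half-open throughout this module.  A cut
position ``c`` means the phosphodiester backbone is severed between
``seq[c-1]`` and ``seq[c]`` on the top strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "IUPAC_CODES",
    "GenomeSequence",
    "RestrictionEnzyme",
    "DigestProfile",
    "HINDIII",
    "find_recognition_sites",
    "digest",
    "total_length",
]

#: IUPAC nucleotide one-letter codes (unambiguous + ambiguity + N).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

Topology = Literal["linear", "circular"]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence with explicit topology.

    Parameters
    ----------
    id
        Label, unique within any collection the genome participates in.
    seq
        Nucleotide string over the IUPAC alphabet; stored uppercase.
    topology
        ``"linear"`` (default — virion DNA) or ``"circular"``.
    """

    id: str
    seq: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: sequence is empty")
        upper = self.seq.upper()
        for offset, base in enumerate(upper):
            if base not in IUPAC_CODES:
                raise ValueError(
                    f"genome {self.id!r}: non-IUPAC character {base!r} "
                    f"at offset {offset}"
                )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "seq", upper)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction endonuclease: recognition site and cut offset.

    ``cut_offset`` is the position of the top-strand cut within the
    recognition site: HindIII (A^AGCTT) has recognition ``AAGCTT`` and
    ``cut_offset`` 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        rec = self.recognition.upper()
        bad = set(rec) - set("ACGT")
        if bad:
            raise ValueError(
                f"enzyme {self.name!r}: recognition must be unambiguous "
                f"ACGT, found {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside "
                f"0..{len(rec)}"
            )
        object.__setattr__(self, "recognition", rec)


#: The enzyme used throughout enterococcal-phage RFLP typing here.
HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1)


@dataclass(frozen=True)
class DigestProfile:
    """Fragment lengths (bp, sorted descending) of one genome × enzyme."""

    genome_id: str
    enzyme: str
    fragments: tuple[int, ...]
    topology_used: Topology
    uncut: bool = field(default=False)

    def __post_init__(self) -> None:
        frags = tuple(sorted(self.fragments, reverse=True))
        if not frags:
            raise ValueError(f"profile {self.genome_id!r}: empty fragment list")
        if frags[-1] < 1:
            raise ValueError(
                f"profile {self.genome_id!r}: fragments must be >= 1 bp"
            )
        object.__setattr__(self, "fragments", frags)


def find_recognition_sites(
    genome: GenomeSequence, enzyme: RestrictionEnzyme
) -> list[int]:
    """Locate all cut positions of ``enzyme`` in ``genome``.

    Matching is exact: an ambiguity code (including N) in the genome never
    matches a recognition base, so sites running through ambiguous stretches
    are dropped rather than expanded.  Palindromic sites are scanned on the
    top strand only.  For circular genomes, sites spanning the origin are
    found by scanning the sequence extended by its first ``len(site)-1``
    bases and mapping cut positions modulo the genome length.

    Returns
    -------
    list of int
        Strictly increasing 0-based cut positions.
    """
    site = enzyme.recognition
    seq = genome.seq
    n = len(seq)
    if genome.topology == "circular" and n >= len(site):
        scan = seq + seq[: len(site) - 1]
    else:
        scan = seq

    cuts: set[int] = set()
    start = scan.find(site)
    while start != -1:
        cuts.add((start + enzyme.cut_offset) % n)
        start = scan.find(site, start + 1)  # overlapping sites all reported
    return sorted(cuts)


def digest(genome: GenomeSequence, enzyme: RestrictionEnzyme) -> DigestProfile:
    """Digest ``genome`` with ``enzyme`` and return its fragment profile.

    A linear genome with *k* cut sites yields *k*+1 fragments (terminal
    fragments included); a circular genome with *k* ≥ 1 sites yields *k*
    fragments.  With no sites the profile is the single full-length
    fragment, flagged ``uncut`` for circular genomes.  Fragment lengths
    always sum to the genome length.
    """
    cuts = find_recognition_sites(genome, enzyme)
    n = len(genome)

    if not cuts:
        return DigestProfile(
            genome_id=genome.id,
            enzyme=enzyme.name,
            fragments=(n,),
            topology_used=genome.topology,
            uncut=genome.topology == "circular",
        )

    if genome.topology == "linear":
        bounds = [0] + cuts + [n]
        lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    else:
        lengths = [b - a for a, b in zip(cuts, cuts[1:])]
        lengths.append(n - cuts[-1] + cuts[0])  # fragment through the origin
    lengths = [x for x in lengths if x > 0]  # cut flush with a terminus

    return DigestProfile(
        genome_id=genome.id,
        enzyme=enzyme.name,
        fragments=tuple(lengths),
        topology_used=genome.topology,
    )


def total_length(profile: DigestProfile) -> int:
    """Sum of fragment lengths — equals the genome length for exact digests."""
    if not profile.fragments:
        raise ValueError("empty fragment list")
    return sum(profile.fragments)
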