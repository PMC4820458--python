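"""Synthetic inputs: random phage-like genomes, sequence evolution along a
known tree, and challenge-assay count tables.

The generator emulates the study conditions of an RFLP-typing panel: phage
genomes in the 17–148 kb range related by a known phylogeny through point
substitutions only (no indels, so digest profiles stay comparable and site
gain/loss carries the phylogenetic signal), and triplicate plate-count /
concentration data with multiplicative (lognormal) noise, control versus
phage-treated.  Everything is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Phylo

from .digest import GenomeSequence

__all__ = [
    "SimulationSpec",
    "random_genome",
    "evolve_on_tree",
    "two_clade_newick",
    "simulate_challenge",
]

_BASES = np.array(list("ACGT"))

#: Enterococcal-phage-like defaults: GC content of E. faecalis phages is
#: around 0.35–0.40; genome lengths span roughly 17–148 kb.
DEFAULT_GC = 0.37
DEFAULT_LENGTH = 40_000


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a genome-panel simulation.

    ``tree`` is a Newick string whose branch lengths are expected
    substitutions per site; its leaf names label the output genomes.
    """

    tree: str
    genome_length: int = DEFAULT_LENGTH
    gc_fraction: float = DEFAULT_GC
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")


def random_genome(
    length: int, gc: float = DEFAULT_GC, seed: int | None = None, id: str = "synthetic"
) -> GenomeSequence:
    """An i.i.d. random genome with P(G) = P(C) = gc/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    seq = rng.choice(_BASES, size=length, p=[at, gc / 2, gc / 2, at])
    return GenomeSequence(id=id, seq="".join(seq), topology="linear")


def _mutate(codes: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor-style point substitutions along one branch.

    Each site mutates with probability 1 − e^(−ℓ); a mutated site changes
    to one of the three other bases uniformly.
    """
    if branch_length < 0:
        raise ValueError("branch lengths must be >= 0")
    if branch_length == 0:
        return codes.copy()
    p = 1.0 - np.exp(-branch_length)
    hit = rng.random(codes.size) < p
    out = codes.copy()
    # uniform choice among the 3 other bases via a shifted offset 1..3
    out[hit] = (codes[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


def evolve_on_tree(root: GenomeSequence, spec: SimulationSpec) -> list[GenomeSequence]:
    """Evolve ``root`` along ``spec.tree`` and return the leaf genomes.

    Substitution-only evolution: sequence length is preserved so restriction
    profiles remain directly comparable across leaves.  Branches are visited
    in the Newick's own order with a single seeded generator, so the result
    is deterministic per (tree, seed).
    """
    tree = Phylo.read(_io.StringIO(spec.tree), "newick")
    rng = np.random.default_rng(spec.seed)
    base_index = {b: i for i, b in enumerate("ACGT")}
    try:
        codes = np.array([base_index[b] for b in root.seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"root genome contains ambiguity code {exc.args[0]!r}; evolution "
            "requires an unambiguous ACGT sequence"
        ) from None

    leaves: list[GenomeSequence] = []

    def descend(clade, codes_in: np.ndarray) -> None:
        bl = clade.branch_length or 0.0
        codes_out = _mutate(codes_in, bl, rng)
        if clade.is_terminal():
            name = clade.name or f"taxon{len(leaves) + 1}"
            leaves.append(
                GenomeSequence(
                    id=name,
                    seq="".join(_BASES[codes_out]),
                    topology=root.topology,
                )
            )
        else:
            for child in clade.clades:
                descend(child, codes_out)

    descend(tree.root, codes)
    return leaves


def two_clade_newick(
    n_per_clade: int = 3,
    within: float = 0.002,
    between: float = 0.05,
    prefixes: tuple[str, str] = ("A", "B"),
) -> str:
    """Newick for two well-separated clades of ``n_per_clade`` leaves each.

    Leaves sit at the end of short ``within`` branches; the two clade stems
    each carry half of the ``between`` divergence.
    """
    if n_per_clade < 2:
        raise ValueError("need at least 2 leaves per clade")
    halves = []
    for prefix in prefixes:
        tips = ",".join(
            f"{prefix}{k}:{within:g}" for k in range(1, n_per_clade + 1)
        )
        halves.append(f"({tips}):{between / 2:g}")
    return f"({halves[0]},{halves[1]});"


def simulate_challenge(
    control_mean: float,
    effect_fraction: float,
    cv: float = 0.1,
    n_replicates: int = 3,
    seed: int | None = None,
    measure: str = "cfu_per_ml",
    timepoint: str = "t15",
) -> pd.DataFrame:
    """Simulate a control-vs-phage challenge table.

    Replicates are lognormal with arithmetic mean ``control_mean`` (or
    ``control_mean × (1 − effect_fraction)`` for the phage group) and
    coefficient of variation ``cv`` — the standard multiplicative noise
    model for plate counts.  Returns a tidy frame with columns condition,
    timepoint, replicate, measure, value.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    if not 0 <= effect_fraction < 1:
        raise ValueError("effect_fraction must lie in [0, 1)")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 3:
        raise ValueError("at least 3 replicates per group")

    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)

    rows = []
    for condition, mean in (
        ("control", control_mean),
        ("phage", control_mean * (1.0 - effect_fraction)),
    ):
        mu = np.log(mean) - sigma2 / 2.0  # arithmetic mean preserved
        values = (
            np.exp(mu + sigma * rng.standard_normal(n_replicates))
            if cv > 0
            else np.full(n_replicates, mean)
        )
        for r, v in enumerate(values, start=1):
            rows.append((condition, timepoint, r, measure, float(v)))
    return pd.DataFrame(
        rows, columns=["condition", "timepoint", "replicate", "measure", "value"]
    )
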