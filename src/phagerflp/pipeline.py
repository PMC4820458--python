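"""End-to-end RFLP typing pipeline: digest → (optional gel) → distances → tree.

Mirrors the typing workflow applied to a panel of phage genomes: virtual
digestion of each genome, optionally a gel round trip (render each digest
as a lane and re-infer band sizes, adding realistic measurement error and
detection losses), band-profile comparison at a relative position
tolerance, and a UPGMA dendrogram written as Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as pio
from .digest import HINDIII, DigestProfile, GenomeSequence, RestrictionEnzyme, digest
from .fingerprint import (
    DEFAULT_TOLERANCE,
    BandProfile,
    DistanceMatrix,
    distance_matrix,
)
from .gel import (
    DETECTION_WINDOW,
    MigrationModel,
    fit_migration_model,
    infer_sizes,
    render_lane,
)
from .upgma import Dendrogram, render_ascii, to_newick, upgma

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("phagerflp")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the typing pipeline, validated up front."""

    enzyme: RestrictionEnzyme = HINDIII
    topology: str = "linear"
    tolerance: float = DEFAULT_TOLERANCE
    coefficient: str = "dice"
    use_gel: bool = False
    gel_model: MigrationModel | None = None
    gel_noise_sd: float = 0.0
    gel_resolution_mm: float = 0.5
    detection_window: tuple[float, float] = DETECTION_WINDOW
    seed: int | None = None
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.coefficient not in ("dice", "jaccard"):
            raise ValueError("coefficient must be 'dice' or 'jaccard'")
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")
        if self.use_gel and self.gel_model is None:
            from .gel import DEFAULT_MODEL

            object.__setattr__(self, "gel_model", DEFAULT_MODEL)


@dataclass
class PipelineResult:
    profiles: list[DigestProfile]
    band_profiles: list[BandProfile]
    distances: DistanceMatrix
    tree: Dendrogram
    newick: str


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    genomes: Sequence[GenomeSequence] | str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full typing pipeline over a genome panel.

    ``genomes`` may be a FASTA path or a pre-built genome list.  With
    ``config.outdir`` set, intermediates (profiles TSV, distance CSV,
    Newick tree, run report) are written there.
    """
    if isinstance(genomes, (str, Path)):
        genomes = pio.read_fasta(genomes, topology=config.topology)
    if len(genomes) < 2:
        raise ValueError("pipeline needs at least 2 genomes to build a tree")

    logger.info(
        "pipeline config: enzyme=%s topology=%s tol=%g coefficient=%s gel=%s",
        config.enzyme.name,
        config.topology,
        config.tolerance,
        config.coefficient,
        config.use_gel,
    )

    profiles = _stage("digest")(
        lambda: [digest(g, config.enzyme) for g in genomes]
    )()
    for p in profiles:
        logger.info(
            "digest %s: %d fragments, %d bp total",
            p.genome_id,
            len(p.fragments),
            sum(p.fragments),
        )

    if config.use_gel:

        def gel_roundtrip() -> list[BandProfile]:
            out = []
            for k, p in enumerate(profiles):
                lane = render_lane(
                    p,
                    config.gel_model,  # type: ignore[arg-type]
                    noise_sd=config.gel_noise_sd,
                    detection=config.detection_window,
                    seed=None if config.seed is None else config.seed + k,
                    resolution_mm=config.gel_resolution_mm,
                )
                sizes = []
                for s, band in zip(
                    infer_sizes(lane, config.gel_model), lane.bands  # type: ignore[arg-type]
                ):
                    sizes.extend([s] * band.multiplicity)
                out.append(
                    BandProfile(id=p.genome_id, sizes=tuple(sizes), source="gel_inferred")
                )
            return out

        band_profiles = _stage("gel")(gel_roundtrip)()
    else:
        band_profiles = [
            BandProfile(id=p.genome_id, sizes=tuple(float(x) for x in p.fragments))
            for p in profiles
        ]

    dm = _stage("fingerprint")(
        lambda: distance_matrix(band_profiles, config.tolerance, config.coefficient)
    )()
    tree = _stage("upgma")(lambda: upgma(dm))()
    newick = to_newick(tree)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.profiles_to_tsv(profiles, outdir / "profiles.tsv")
        pio.write_band_profiles(band_profiles, outdir / "bands.tsv")
        pio.matrix_to_csv(dm, outdir / "distances.csv")
        (outdir / "tree.nwk").write_text(newick + "\n")
        report = [
            f"enzyme\t{config.enzyme.name} ({config.enzyme.recognition})",
            f"topology\t{config.topology}",
            f"tolerance\t{config.tolerance}",
            f"coefficient\t{config.coefficient}",
            f"gel_roundtrip\t{config.use_gel}",
            f"n_genomes\t{len(genomes)}",
        ]
        for p in profiles:
            report.append(
                f"genome\t{p.genome_id}\tfragments={len(p.fragments)}\t"
                f"total_bp={sum(p.fragments)}"
            )
        report.append("")
        report.append(render_ascii(tree))
        (outdir / "report.txt").write_text("\n".join(report) + "\n")

    return PipelineResult(
        profiles=list(profiles),
        band_profiles=band_profiles,
        distances=dm,
        tree=tree,
        newick=newick,
    )
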