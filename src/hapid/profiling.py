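"""Community profiling from HAP-database search results.

Turns FDR-filtered PSMs into a spectrum -> genomes incidence map, ranks
genomes by greedy set cover until a target fraction of identified
spectra is covered, and rolls identified spectra up to taxonomic clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .search_engine import PSM
from .sequence_db import expand_protein_genomes

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: spectrum_id -> set of genomes whose proteins contain the identified peptide
IncidenceMap = dict[str, set[str]]


@dataclass
class GenomeSelection:
    """Ordered greedy genome selection with per-step coverage."""

    steps: list[tuple[str, int, float]]  # (genome_id, newly_covered, cumulative_fraction)
    coverage_threshold: float
    n_spectra: int

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _, _ in self.steps]

    @property
    def final_fraction(self) -> float:
        return self.steps[-1][2] if self.steps else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["genome_id", "newly_covered", "cumulative_fraction"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_incidence(
    psms: Sequence[PSM],
    registry: Mapping[str, str] | None = None,
    dedup_map: Mapping[str, str] | None = None,
    unique_only: bool = False,
) -> IncidenceMap:
    """Spectrum -> genome incidence from FDR-filtered target PSMs.

    When ``registry`` is given, genome credit is recomputed from protein
    ids (dedup_map-expanded so genomes whose identical HAP was collapsed
    are still credited); otherwise the PSMs' genome_ids are used.
    With ``unique_only`` a spectrum is kept only if it maps to exactly
    one genome (the alternative reading of "unique spectra").
    """
    inc: IncidenceMap = {}
    n_dropped = 0
    for psm in psms:
        if psm.is_decoy:
            raise ValueError(
                f"decoy PSM {psm.spectrum_id} in incidence input; "
                f"apply FDR filtering first"
            )
        if registry is not None:
            genomes = expand_protein_genomes(psm.protein_ids, registry, dedup_map)
        else:
            genomes = set(psm.genome_ids)
        if not genomes:
            n_dropped += 1
            continue
        if unique_only and len(genomes) != 1:
            continue
        inc[psm.spectrum_id] = genomes
    if n_dropped:
        logger.info("dropped %d spectra mapping to no registered genome", n_dropped)
    return inc


def genome_spectral_counts(inc: IncidenceMap) -> dict[str, int]:
    """Number of identified spectra each genome can explain."""
    counts: dict[str, int] = {}
    for genomes in inc.values():
        for g in genomes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def greedy_cover(inc: IncidenceMap, coverage_threshold: float = 0.8) -> GenomeSelection:
    """Greedy minimal genome set explaining the identified spectra.

    Repeatedly picks the genome covering the most not-yet-covered
    spectra (ties broken by lexicographic genome id), until the covered
    fraction reaches the threshold or no genome adds coverage. Each
    spectrum counts once, toward the first genome that covers it.
    """
    if not inc:
        raise ValueError("no identified spectra to profile")
    if not 0 < coverage_threshold <= 1:
        raise ValueError(
            f"coverage threshold must be in (0, 1], got {coverage_threshold}"
        )
    n_total = len(inc)
    remaining: dict[str, set[str]] = {}  # genome -> uncovered spectra
    for sid, genomes in inc.items():
        for g in genomes:
            remaining.setdefault(g, set()).add(sid)
    steps: list[tuple[str, int, float]] = []
    covered = 0
    while covered / n_total < coverage_threshold:
        best_genome = None
        best_gain = 0
        for g in sorted(remaining):
            gain = len(remaining[g])
            if gain > best_gain:
                best_genome, best_gain = g, gain
        if best_genome is None or best_gain == 0:
            break
        newly = remaining.pop(best_genome)
        covered += len(newly)
        steps.append((best_genome, len(newly), covered / n_total))
        for g in list(remaining):
            remaining[g] -= newly
            if not remaining[g]:
                del remaining[g]
    return GenomeSelection(steps=steps, coverage_threshold=coverage_threshold, n_spectra=n_total)


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Taxonomy TSV: genome_id <tab> semicolon-delimited lineage
    (domain;phylum;class;order;family;genus;species)."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0] == "genome_id":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 columns")
            names = parts[1].split(";")
            out[parts[0]] = {
                rank: names[j].strip() if j < len(names) and names[j].strip() else "unclassified"
                for j, rank in enumerate(RANKS)
            }
    return out


def taxonomic_profile(
    psms: Sequence[PSM],
    taxonomy: Mapping[str, Mapping[str, str]],
    rank: str = "order",
    min_unique_peptides: int = 0,
    genomes: Sequence[str] | None = None,
    registry: Mapping[str, str] | None = None,
    dedup_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-clade spectral counts and percentages at one taxonomic rank.

    Genomes are restricted either to an explicit list (e.g. the greedy
    selection) or to those with at least ``min_unique_peptides`` distinct
    identified peptides. A spectrum is credited to each genome that can
    explain it; percentages are over all credited (spectrum, genome)
    pairs and sum to 100.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {', '.join(RANKS)}")
    inc = build_incidence(psms, registry=registry, dedup_map=dedup_map)
    peptides_per_genome: dict[str, set[str]] = {}
    for psm in psms:
        genomes_of = inc.get(psm.spectrum_id, set())
        for g in genomes_of:
            peptides_per_genome.setdefault(g, set()).add(psm.peptide)
    if genomes is not None:
        allowed = set(genomes)
    else:
        allowed = {
            g
            for g, peps in peptides_per_genome.items()
            if len(peps) >= min_unique_peptides
        }
    counts: dict[str, int] = {}
    genome_counts: dict[str, int] = {}
    for sid, gs in inc.items():
        for g in gs & allowed:
            clade = taxonomy.get(g, {}).get(rank, "unclassified")
            counts[clade] = counts.get(clade, 0) + 1
            genome_counts[g] = genome_counts.get(g, 0) + 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "clade": sorted(counts),
            "n_spectra": [counts[c] for c in sorted(counts)],
        }
    )
    df["percent"] = 100.0 * df["n_spectra"] / total if total else 0.0
    return df.sort_values("n_spectra", ascending=False, ignore_index=True)
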