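"""Evaluation metrics for identification runs.

Consistency rate between nested-database searches, spectrum
identification rate, I/L-blind peptide set overlap, per-protein spectral
support with per-genome summaries, expressed-operon detection from gene
loci, and the database-reduction arithmetic for a genome collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .search_engine import PSM

logger = logging.getLogger(__name__)

_IL_TABLE = str.maketrans("I", "L")


def il_canonical(peptide: str) -> str:
    """Map I to L: leucine and isoleucine are isobaric and cannot be
    distinguished by mass spectrometry."""
    return peptide.translate(_IL_TABLE)


def consistency_rate(
    psms_small: Sequence[PSM],
    psms_big: Sequence[PSM],
    il_blind: bool = True,
    mod_blind: bool = True,
) -> tuple[float, int, int]:
    """Fraction of shared-spectrum PSMs whose peptide is unchanged when
    the database grows (the small database must be nested in the big one).

    Returns (rate, n_same, n_shared). By default peptides are compared
    I/L-blind and ignoring modification placement; strict mode compares
    the exact modified peptide.
    """
    def key(p: PSM) -> tuple:
        pep = il_canonical(p.peptide) if il_blind else p.peptide
        return (pep,) if mod_blind else (pep, tuple(sorted(p.modifications)))

    small = {p.spectrum_id: key(p) for p in psms_small}
    big = {p.spectrum_id: key(p) for p in psms_big}
    shared = small.keys() & big.keys()
    if not shared:
        raise ValueError(
            "no spectra identified in both runs; consistency rate is undefined "
            "(check that the runs searched the same spectra)"
        )
    n_same = sum(1 for sid in shared if small[sid] == big[sid])
    return n_same / len(shared), n_same, len(shared)


def identification_rate(n_identified: int, n_spectra: int) -> float:
    """Percent of acquired spectra assigned an FDR-passing peptide."""
    if n_spectra <= 0:
        raise ValueError("total spectrum count must be positive")
    if not 0 <= n_identified <= n_spectra:
        raise ValueError(
            f"identified count {n_identified} outside [0, {n_spectra}]"
        )
    return 100.0 * n_identified / n_spectra


def peptide_overlap(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, int, int]:
    """(only A, shared, only B) peptide counts after I/L canonicalization."""
    a = {il_canonical(p) for p in set_a}
    b = {il_canonical(p) for p in set_b}
    return len(a - b), len(a & b), len(b - a)


def protein_support(psms: Sequence[PSM]) -> dict[str, int]:
    """Distinct spectra per protein; a spectrum is credited to every
    protein containing its peptide."""
    spectra_per_protein: dict[str, set[str]] = {}
    for psm in psms:
        for pid in psm.protein_ids:
            spectra_per_protein.setdefault(pid, set()).add(psm.spectrum_id)
    return {p: len(s) for p, s in spectra_per_protein.items()}


def genome_support_summary(
    psms: Sequence[PSM],
    proteins_per_genome: Mapping[str, int],
    registry: Mapping[str, str],
    min_spectra: int = 1,
) -> pd.DataFrame:
    """Per genome: proteins with >= min_spectra supporting spectra and
    the percent of the genome's putative proteins that represents."""
    support = protein_support(psms)
    per_genome: dict[str, int] = {}
    for pid, n in support.items():
        if n >= min_spectra and pid in registry:
            g = registry[pid]
            per_genome[g] = per_genome.get(g, 0) + 1
    rows = []
    for g in sorted(proteins_per_genome):
        n_supported = per_genome.get(g, 0)
        n_total = proteins_per_genome[g]
        rows.append(
            {
                "genome_id": g,
                "n_proteins": n_total,
                "n_supported": n_supported,
                "percent_supported": 100.0 * n_supported / n_total if n_total else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expressed operons


@dataclass(frozen=True)
class GeneLocus:
    """A gene with 1-based inclusive coordinates and its spectral support."""

    gene_id: str
    protein_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    spectra_count: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


def read_loci_tsv(path: str | Path) -> list[GeneLocus]:
    """6/7-column TSV: gene_id, protein_id, contig_id, start, end, strand
    [, spectra_count]."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "protein_id", "contig_id", "start", "end", "strand"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"loci table {path}: missing column {col!r}")
    if "spectra_count" not in df.columns:
        df["spectra_count"] = 0
    return [
        GeneLocus(
            str(r.gene_id), str(r.protein_id), str(r.contig_id),
            int(r.start), int(r.end), str(r.strand), int(r.spectra_count),
        )
        for r in df.itertuples(index=False)
    ]


def detect_expressed_operons(
    loci: Sequence[GeneLocus],
    max_gap: int = 100,
    min_avg_spectra: float = 10.0,
) -> list[list[GeneLocus]]:
    """Chains of co-expressed neighboring genes (putative operons).

    Consecutive genes on the same contig and strand are chained while the
    intergenic gap (start of next minus end of previous minus one, for
    1-based inclusive coordinates) is at most ``max_gap``; overlapping
    genes count as gap 0. Maximal chains with at least two genes whose
    mean spectral support is strictly greater than ``min_avg_spectra``
    are reported, sorted by (contig, start) so the result is independent
    of input order.
    """
    clusters: list[list[GeneLocus]] = []
    ordered = sorted(loci, key=lambda g: (g.contig_id, g.strand, g.start, g.end))
    chain: list[GeneLocus] = []

    def flush() -> None:
        if len(chain) >= 2:
            mean = sum(g.spectra_count for g in chain) / len(chain)
            if mean > min_avg_spectra:
                clusters.append(list(chain))

    for gene in ordered:
        if chain and gene.contig_id == chain[-1].contig_id and gene.strand == chain[-1].strand:
            gap = gene.start - chain[-1].end - 1
            if gap < 0:
                logger.info(
                    "overlapping genes %s/%s treated as gap 0",
                    chain[-1].gene_id,
                    gene.gene_id,
                )
                gap = 0
            if gap <= max_gap:
                chain.append(gene)
                continue
        flush()
        chain = [gene]
    flush()
    clusters.sort(key=lambda c: (c[0].contig_id, c[0].start))
    return clusters


# ---------------------------------------------------------------------------
# Collection arithmetic


def collection_summary(
    genome_counts: Mapping[str, int],
    protein_counts: Mapping[str, int],
    n_hapdb: int,
    n_searchable_proteins: int | None = None,
) -> dict[str, float]:
    """Database-reduction arithmetic for a genome collection.

    Sums per-source genome and putative-protein counts and reports what
    fraction of the searchable proteins the HAP database represents —
    the number that quantifies how much smaller the profiling search
    space is than the full collection.
    """
    n_genomes = sum(genome_counts.values())
    n_proteins = sum(protein_counts.values())
    denom = n_searchable_proteins if n_searchable_proteins is not None else n_proteins
    if denom <= 0 or n_hapdb < 0:
        raise ValueError("counts must be non-negative with a positive denominator")
    return {
        "n_genomes": float(n_genomes),
        "n_proteins": float(n_proteins),
        "hapdb_percent": 100.0 * n_hapdb / denom,
    }
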