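"""Two-step pipeline orchestration.

Step 1 (profiling): search spectra against the HAP-only database, filter
at the target FDR, and greedily select the minimal genome set covering
the configured fraction of identified spectra. Step 2 (expanded
search): search the same spectra against all proteins of the selected
genomes plus every HAP with spectral support, filter at the target FDR,
and report only the second step's peptides as the final result — the
two steps are never merged, so the final FDR is estimated within a
single search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .fdr import FDRResult, control_fdr
from .profiling import GenomeSelection, build_incidence, greedy_cover
from .search_engine import PSM, SearchParams, best_per_spectrum, search
from .sequence_db import (
    DEFAULT_DECOY_PREFIX,
    ProteinRecord,
    SearchDatabase,
    build_database,
    build_hapdb,
    genome_registry,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the two-step pipeline."""

    search: SearchParams = field(default_factory=SearchParams)
    target_fdr: float = 0.01
    coverage_threshold: float = 0.8
    min_hap_support: int = 1  # FDR-passing PSMs needed to carry a HAP forward
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    fdr_estimator: str = "d/t"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        search_raw = raw.pop("search", {})
        for key in ("isotope_error_range", "charge_range"):
            if key in search_raw:
                search_raw[key] = tuple(search_raw[key])
        for key in ("fixed_mods", "var_mods"):
            if key in search_raw:
                search_raw[key] = tuple(
                    (str(r), float(d)) for r, d in search_raw[key]
                )
        return cls(search=SearchParams(**search_raw), **raw)


@dataclass
class PipelineResult:
    """Everything the two-step run produced."""

    hapdb: SearchDatabase
    step1_psms: list[PSM]
    step1_fdr: FDRResult
    selection: GenomeSelection
    expanded_db: SearchDatabase
    step2_psms: list[PSM]
    step2_fdr: FDRResult
    peptides: pd.DataFrame  # final peptide table (step 2 only)
    n_spectra: int

    @property
    def identification_rate(self) -> float:
        """Percent of acquired spectra with an FDR-passing peptide."""
        return 100.0 * len(self.step2_psms) / self.n_spectra


def build_expanded_db(
    selection: GenomeSelection | Sequence[str],
    supported_haps: set[str],
    records: Sequence[ProteinRecord],
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> SearchDatabase:
    """Step-2 database: all proteins of the selected genomes plus every
    spectral-supported HAP (even from unselected genomes)."""
    genome_ids = (
        selection.genome_ids if isinstance(selection, GenomeSelection) else list(selection)
    )
    if not genome_ids:
        raise ValueError("empty genome selection; cannot build expanded database")
    selected = set(genome_ids)
    chosen = [
        r
        for r in records
        if not r.is_decoy
        and (r.genome_id in selected or r.protein_id in supported_haps)
    ]
    return build_database(chosen, decoy_prefix=decoy_prefix)


def supported_hap_ids(
    step1_psms: Sequence[PSM],
    dedup_map: Mapping[str, str] | None = None,
    min_support: int = 1,
) -> set[str]:
    """HAP proteins with at least ``min_support`` FDR-passing step-1 PSMs.

    Collapsed duplicates of a supported representative are supported too,
    so identical HAPs from unselected genomes enter the expanded database
    under their own genome attribution.
    """
    counts: dict[str, int] = {}
    for psm in step1_psms:
        for pid in psm.protein_ids:
            counts[pid] = counts.get(pid, 0) + 1
    supported = {p for p, c in counts.items() if c >= min_support}
    if dedup_map:
        supported |= {rm for rm, kept in dedup_map.items() if kept in supported}
    return supported


def run_two_step(
    spectra: Sequence,
    records: Sequence[ProteinRecord],
    config: PipelineConfig | None = None,
    external_step1: Sequence[PSM] | None = None,
    external_step2: Sequence[PSM] | None = None,
) -> PipelineResult:
    """Run the full two-step identification.

    ``records`` is the whole genome collection with HAP flags already
    set. External PSM lists (from MS-GF+, X! Tandem, ...) can replace
    either built-in search; downstream behavior is identical.
    """
    config = config or PipelineConfig()
    registry = genome_registry(records)

    # ---- step 1: profiling against the HAP database
    hapdb = build_hapdb(records, decoy_prefix=config.decoy_prefix)
    if external_step1 is not None:
        step1_raw = best_per_spectrum(external_step1)
    else:
        step1_raw = search(spectra, hapdb, config.search, registry=registry)
    step1_psms, step1_fdr = control_fdr(
        step1_raw, target_fdr=config.target_fdr, estimator=config.fdr_estimator
    )
    logger.info(
        "step 1: %d/%d spectra identified at %.2g FDR",
        len(step1_psms),
        len(spectra),
        config.target_fdr,
    )

    inc = build_incidence(step1_psms, registry=registry, dedup_map=hapdb.dedup_map)
    if not inc:
        raise RuntimeError(
            "profiling step identified no spectra; cannot select genomes"
        )
    selection = greedy_cover(inc, coverage_threshold=config.coverage_threshold)
    logger.info(
        "greedy selection: %d genomes covering %.1f%% of identified spectra",
        len(selection.steps),
        100 * selection.final_fraction,
    )

    # ---- step 2: expanded search
    supported = supported_hap_ids(
        step1_psms, dedup_map=hapdb.dedup_map, min_support=config.min_hap_support
    )
    expanded_db = build_expanded_db(
        selection, supported, records, decoy_prefix=config.decoy_prefix
    )
    if external_step2 is not None:
        step2_raw = best_per_spectrum(external_step2)
    else:
        step2_raw = search(spectra, expanded_db, config.search, registry=registry)
    step2_psms, step2_fdr = control_fdr(
        step2_raw, target_fdr=config.target_fdr, estimator=config.fdr_estimator
    )
    logger.info(
        "step 2: %d/%d spectra identified at %.2g FDR",
        len(step2_psms),
        len(spectra),
        config.target_fdr,
    )

    return PipelineResult(
        hapdb=hapdb,
        step1_psms=step1_psms,
        step1_fdr=step1_fdr,
        selection=selection,
        expanded_db=expanded_db,
        step2_psms=step2_psms,
        step2_fdr=step2_fdr,
        peptides=peptide_table(step2_psms),
        n_spectra=len(spectra),
    )


def peptide_table(psms: Sequence[PSM]) -> pd.DataFrame:
    """Final peptide table: one row per peptide string (I/L preserved),
    with spectral count, proteins, genomes and best score."""
    rows: dict[str, dict] = {}
    for psm in psms:
        row = rows.get(psm.peptide)
        if row is None:
            rows[psm.peptide] = {
                "peptide": psm.peptide,
                "n_spectra": 1,
                "proteins": set(psm.protein_ids),
                "genomes": set(psm.genome_ids),
                "best_score": psm.score,
            }
        else:
            row["n_spectra"] += 1
            row["proteins"] |= psm.protein_ids
            row["genomes"] |= psm.genome_ids
            row["best_score"] = max(row["best_score"], psm.score)
    df = pd.DataFrame(
        [
            {
                "peptide": r["peptide"],
                "n_spectra": r["n_spectra"],
                "proteins": ";".join(sorted(r["proteins"])),
                "genomes": ";".join(sorted(r["genomes"])),
                "best_score": r["best_score"],
            }
            for r in rows.values()
        ]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["peptide", "n_spectra", "proteins", "genomes", "best_score"]
        )
    return df.sort_values(
        ["n_spectra", "peptide"], ascending=[False, True], ignore_index=True
    )
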