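"""Protein search databases keyed by genome.

Builds the two databases the pipeline searches: the HAP database (only
ribosomal proteins / elongation factors from every genome) and the
expanded per-sample database. Both are deduplicated at 100% sequence
identity and decoy-augmented by full sequence reversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .constants import VALID_RESIDUES

logger = logging.getLogger(__name__)

DEFAULT_DECOY_PREFIX = "XXX_"


@dataclass
class ProteinRecord:
    """One protein sequence with its genome of origin.

    ``annotation`` is the free-text product description from the FASTA
    header; ``is_hap`` marks high-abundance proteins (ribosomal proteins
    and elongation factors); ``is_decoy`` marks reversed decoy entries.
    """

    protein_id: str
    genome_id: str
    sequence: str
    annotation: str = ""
    is_hap: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: invalid residue(s) "
                f"{''.join(sorted(bad))!r} (U and O are rejected, X is allowed)"
            )


@dataclass
class SearchDatabase:
    """Deduplicated target records plus their reversed decoys.

    ``dedup_map`` sends each removed duplicate protein_id to the retained
    representative, so downstream profiling can credit every genome that
    carried an identical sequence.
    """

    records: list[ProteinRecord]
    decoys: list[ProteinRecord]
    dedup_map: dict[str, str] = field(default_factory=dict)

    @property
    def all_records(self) -> list[ProteinRecord]:
        return self.records + self.decoys

    def write_fasta(self, path: str | Path, include_decoys: bool = True) -> None:
        recs = self.all_records if include_decoys else self.records
        with open(path, "w") as fh:
            for r in recs:
                header = f">{r.protein_id}"
                if r.annotation:
                    header += f" {r.annotation}"
                fh.write(f"{header}\n{r.sequence}\n")

    def write_dedup_map(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("removed_protein_id\tretained_protein_id\n")
            for removed, kept in sorted(self.dedup_map.items()):
                fh.write(f"{removed}\t{kept}\n")


def load_fasta_collection(
    paths: Sequence[str | Path], genome_ids: Sequence[str]
) -> list[ProteinRecord]:
    """Read one FASTA per genome into ProteinRecords.

    The genome_id of every entry in ``paths[i]`` is ``genome_ids[i]``; the
    annotation is the description line after the first whitespace.
    """
    if len(paths) != len(genome_ids):
        raise ValueError(
            f"{len(paths)} paths but {len(genome_ids)} genome ids"
        )
    records: list[ProteinRecord] = []
    for path, gid in zip(paths, genome_ids):
        path = Path(path)
        if not path.is_file():
            raise IOError(f"cannot read FASTA file: {path}")
        entries = list(SeqIO.parse(str(path), "fasta"))
        if not entries:
            raise ValueError(f"empty FASTA file: {path}")
        for entry in entries:
            annotation = entry.description.split(None, 1)
            records.append(
                ProteinRecord(
                    protein_id=entry.id,
                    genome_id=gid,
                    sequence=str(entry.seq).upper(),
                    annotation=annotation[1] if len(annotation) > 1 else "",
                )
            )
    return records


def load_genome_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (protein_id, genome_id) into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[:2] == ["protein_id", "genome_id"]:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1} has fewer than 2 columns")
            out[parts[0]] = parts[1]
    return out


def deduplicate_exact(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Collapse records with identical sequences (100% identity).

    The first record seen with a given sequence is retained; its HAP flag
    becomes the OR of all duplicates' flags. Returns the retained records
    and the removed_id -> retained_id map.
    """
    if not records:
        raise ValueError("no records to deduplicate")
    by_seq: dict[str, ProteinRecord] = {}
    kept: list[ProteinRecord] = []
    dedup_map: dict[str, str] = {}
    for rec in records:
        rep = by_seq.get(rec.sequence)
        if rep is None:
            rep = replace(rec)
            by_seq[rec.sequence] = rep
            kept.append(rep)
        else:
            dedup_map[rec.protein_id] = rep.protein_id
            rep.is_hap = rep.is_hap or rec.is_hap
    return kept, dedup_map


def generate_decoys(
    records: Sequence[ProteinRecord], prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target record.

    Decoy ids are the target id with ``prefix`` prepended; the genome id
    is mirrored so decoy matches can be traced during diagnostics.
    """
    existing = {r.protein_id for r in records}
    decoys: list[ProteinRecord] = []
    for rec in records:
        decoy_id = prefix + rec.protein_id
        if decoy_id in existing:
            raise ValueError(
                f"decoy id {decoy_id!r} collides with an existing protein id; "
                f"choose a different prefix"
            )
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            logger.info("palindromic sequence: decoy equals target for %s", rec.protein_id)
        decoys.append(
            ProteinRecord(
                protein_id=decoy_id,
                genome_id=rec.genome_id,
                sequence=rev,
                annotation=rec.annotation,
                is_hap=rec.is_hap,
                is_decoy=True,
            )
        )
    return decoys


def build_database(
    records: Sequence[ProteinRecord], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> SearchDatabase:
    """Deduplicate and decoy-augment a record set into a SearchDatabase."""
    kept, dedup_map = deduplicate_exact(records)
    decoys = generate_decoys(kept, prefix=decoy_prefix)
    return SearchDatabase(records=kept, decoys=decoys, dedup_map=dedup_map)


def build_hapdb(
    records: Sequence[ProteinRecord], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> SearchDatabase:
    """The step-1 database: HAPs only, from every genome."""
    haps = [r for r in records if r.is_hap and not r.is_decoy]
    if not haps:
        raise ValueError(
            "no proteins are flagged as HAPs; run HAP extraction "
            "(keyword or domain-scan selection) before building the HAP database"
        )
    return build_database(haps, decoy_prefix=decoy_prefix)


def genome_registry(records: Iterable[ProteinRecord]) -> dict[str, str]:
    """protein_id -> genome_id over *all* input records (pre-dedup).

    Kept alongside the dedup_map so that a peptide matched to a retained
    representative can be credited to every genome carrying the identical
    sequence.
    """
    return {r.protein_id: r.genome_id for r in records}


def expand_protein_genomes(
    protein_ids: Iterable[str],
    registry: Mapping[str, str],
    dedup_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Genomes of the given proteins, including genomes whose identical
    duplicate was collapsed onto one of them."""
    ids = set(protein_ids)
    if dedup_map:
        for removed, kept in dedup_map.items():
            if kept in ids:
                ids.add(removed)
    return {registry[p] for p in ids if p in registry}
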