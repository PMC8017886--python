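"""Flagging of high-abundance proteins (HAPs).

Ribosomal proteins and translation elongation factors are flagged either
from free-text product annotations (keyword match) or from an HMM
domain-scan table restricted to a curated list of profiles at a strict
E-value cutoff. When both kinds of evidence are available the union is
taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_db import ProteinRecord

DEFAULT_KEYWORDS = ("ribosomal protein", "elongation factor")
DEFAULT_E_CUTOFF = 1e-10


@dataclass(frozen=True)
class DomainHit:
    """One row of a domain-scan result table."""

    protein_id: str
    profile_name: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(
                f"domain hit {self.protein_id}/{self.profile_name}: "
                f"E-value must be positive, got {self.e_value}"
            )


def select_haps_by_keyword(
    records: Sequence[ProteinRecord],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> set[str]:
    """Protein ids whose annotation contains any keyword (case-insensitive
    substring match)."""
    if not keywords:
        raise ValueError("keyword list must not be empty")
    lowered = [k.lower() for k in keywords]
    return {
        r.protein_id
        for r in records
        if any(k in r.annotation.lower() for k in lowered)
    }


def select_haps_by_domain(
    hits: Iterable[DomainHit],
    allowed_profiles: set[str] | frozenset[str],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> set[str]:
    """Protein ids with at least one hit to an allowed profile at
    E-value <= e_cutoff."""
    if e_cutoff <= 0:
        raise ValueError(f"E-value cutoff must be positive, got {e_cutoff}")
    if not allowed_profiles:
        raise ValueError("allowed_profiles must not be empty")
    return {
        h.protein_id
        for h in hits
        if h.profile_name in allowed_profiles and h.e_value <= e_cutoff
    }


def default_profile_list() -> set[str]:
    """The shipped ribosomal-protein / elongation-factor profile names."""
    return read_profile_list(Path(__file__).parent / "data" / "hap_profiles.txt")


def read_profile_list(path: str | Path) -> set[str]:
    """One profile name per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                out.add(name)
    return out


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Parse a domain-scan table: HMMER3 per-domain tabular output
    (``hmmscan --domtblout``) or a 3-column TSV fallback
    (protein_id, profile_name, e_value).

    In the HMMER dialect the profile is column 1, the query protein is
    column 4 and the independent (i-)E-value of the domain is column 13.
    The TSV fallback is detected by tab delimiters and exactly three
    fields per row.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line:
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 tab-separated "
                        f"columns (protein_id, profile_name, e_value)"
                    )
                if lineno == 1 and parts[0] == "protein_id":
                    continue
                hits.append(DomainHit(parts[0], parts[1], float(parts[2])))
            else:
                parts = line.split()
                if len(parts) < 13:
                    raise ValueError(
                        f"{path}: line {lineno}: not an HMMER3 per-domain "
                        f"table row ({len(parts)} fields)"
                    )
                # target name, --, --, query name, ..., i-Evalue at index 12
                hits.append(DomainHit(parts[3], parts[0], float(parts[12])))
    return hits


def flag_haps(
    records: Sequence[ProteinRecord],
    keyword_ids: set[str] | None = None,
    domain_ids: set[str] | None = None,
) -> set[str]:
    """Set ``is_hap`` on records in place; the flag is the union of the
    evidence sets. Returns the flagged id set."""
    selected = (keyword_ids or set()) | (domain_ids or set())
    for r in records:
        if r.protein_id in selected:
            r.is_hap = True
    return selected
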