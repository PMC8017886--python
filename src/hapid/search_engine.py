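"""Desk-scale peptide-spectrum matching.

In-silico tryptic digestion (strict trypsin and trypsin/P, full and
semi-tryptic), monoisotopic mass computation with fixed/variable
modifications, a mass-indexed candidate store, and a hyperscore-style
b/y fragment scorer. An adapter reads externally produced PSM tables so
a full search engine (MS-GF+, X! Tandem) can drive the pipeline instead.

The scorer counts singly charged b and y ions matched within a ppm
tolerance and scores ln(Nb!) + ln(Ny!) + ln(1 + sum of matched
intensities); candidates are pre-filtered by precursor mass within a ppm
window allowing integer isotope errors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    CARBAMIDOMETHYL,
    ISOTOPE_SPACING,
    MONO_RESIDUE,
    OXIDATION,
    PROTON,
    WATER,
)
from .sequence_db import (
    DEFAULT_DECOY_PREFIX,
    SearchDatabase,
    expand_protein_genomes,
)

logger = logging.getLogger(__name__)


@dataclass
class SearchParams:
    """Search-engine settings.

    Defaults follow common high-resolution instrument settings: 15 ppm
    precursor tolerance with isotope errors -1..2, 20 ppm fragment
    tolerance, trypsin/P with up to 2 missed cleavages, semi-tryptic
    digestion, fixed carbamidomethyl C, variable oxidation M with at most
    3 modifications per peptide, precursor charges 1-7.
    """

    precursor_tol_ppm: float = 15.0
    isotope_error_range: tuple[int, int] = (-1, 2)
    fragment_tol_ppm: float = 20.0
    missed_cleavages_max: int = 2
    trypsin_p: bool = True
    semi_tryptic: bool = True
    max_var_mods: int = 3
    fixed_mods: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)
    var_mods: tuple[tuple[str, float], ...] = (("M", OXIDATION),)
    charge_range: tuple[int, int] = (1, 7)
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    min_peaks: int = 10

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.isotope_error_range[0] > self.isotope_error_range[1]:
            raise ValueError("isotope error range must be ordered")
        if self.charge_range[0] > self.charge_range[1]:
            raise ValueError("charge range must be ordered")


@dataclass
class PeptideCandidate:
    """A digested peptide with provenance and modification state."""

    sequence: str
    protein_ids: frozenset[str] = frozenset()
    missed_cleavages: int = 0
    semi_tryptic: bool = False
    modifications: tuple[tuple[int, float], ...] = ()  # (1-based pos, delta Da)


@dataclass
class PSM:
    """Best peptide-spectrum match for one spectrum."""

    spectrum_id: str
    peptide: str
    score: float
    is_decoy: bool
    protein_ids: frozenset[str] = frozenset()
    genome_ids: frozenset[str] = frozenset()
    modifications: tuple[tuple[int, float], ...] = ()


# ---------------------------------------------------------------------------
# Digestion


def _cleavage_boundaries(sequence: str, trypsin_p: bool) -> list[int]:
    """Cut positions (string indices where a new peptide may start),
    including 0 and len(sequence). Trypsin cuts C-terminal to K/R; the
    strict dialect suppresses cleavage before proline."""
    bounds = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and (trypsin_p or sequence[i + 1] != "P"):
            bounds.append(i + 1)
    bounds.append(len(sequence))
    return bounds


def digest(sequence: str, params: SearchParams) -> list[PeptideCandidate]:
    """All peptides of one protein under the configured cleavage rules.

    Fully tryptic peptides span consecutive cleavage boundaries with at
    most ``missed_cleavages_max`` internal sites; semi-tryptic mode adds
    every peptide with exactly one tryptic terminus (prefixes and
    suffixes of the fully tryptic spans). Duplicate strings within one
    protein are collapsed, keeping the lowest missed-cleavage count.
    """
    bounds = _cleavage_boundaries(sequence, params.trypsin_p)
    lo, hi = params.min_peptide_length, params.max_peptide_length
    best: dict[str, tuple[int, bool]] = {}  # seq -> (missed, semi)

    def _offer(pep: str, missed: int, semi: bool) -> None:
        prev = best.get(pep)
        if prev is None or (missed, semi) < prev:
            best[pep] = (missed, semi)

    n_bounds = len(bounds)
    for a in range(n_bounds - 1):
        start = bounds[a]
        for b in range(a + 1, min(a + params.missed_cleavages_max + 2, n_bounds)):
            end = bounds[b]
            missed = b - a - 1
            span = sequence[start:end]
            if lo <= len(span) <= hi:
                _offer(span, missed, False)
            if params.semi_tryptic:
                # prefixes keep the tryptic N-terminus, suffixes the C-terminus
                inner = set(bounds[a + 1 : b])
                for e in range(start + lo, min(end, start + hi + 1)):
                    if e != end:
                        m = sum(1 for x in inner if x < e)
                        _offer(sequence[start:e], m, True)
                for s in range(max(start + 1, end - hi), end - lo + 1):
                    if s != start:
                        m = sum(1 for x in inner if x > s)
                        _offer(sequence[s:end], m, True)
    return [
        PeptideCandidate(sequence=pep, missed_cleavages=m, semi_tryptic=s)
        for pep, (m, s) in best.items()
    ]


# ---------------------------------------------------------------------------
# Masses


def peptide_mass(
    sequence: str,
    modifications: Iterable[tuple[int, float]] = (),
    fixed_mods: Iterable[tuple[str, float]] = (),
    unknown_residue_mass: float | None = None,
) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas.

    ``fixed_mods`` adds a delta for every occurrence of a residue;
    ``modifications`` are explicit (1-based position, delta) pairs.
    Residue X has no defined mass unless ``unknown_residue_mass`` is set.
    """
    total = WATER
    for aa in sequence:
        m = MONO_RESIDUE.get(aa)
        if m is None:
            if aa == "X" and unknown_residue_mass is not None:
                m = unknown_residue_mass
            else:
                raise ValueError(
                    f"residue {aa!r} has no defined monoisotopic mass"
                )
        total += m
    for residue, delta in fixed_mods:
        total += sequence.count(residue) * delta
    for pos, delta in modifications:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide")
        total += delta
    return total


# ---------------------------------------------------------------------------
# Candidate index

_MAX_VARIANTS_PER_PEPTIDE = 64  # cap on variable-mod combinations


@dataclass
class _Entry:
    sequence: str
    modifications: tuple[tuple[int, float], ...]
    mass: float
    protein_ids: frozenset[str]
    has_target: bool


class PeptideIndex:
    """Digested peptides of a search database, indexed by neutral mass."""

    def __init__(self, entries: list[_Entry]):
        entries.sort(key=lambda e: (e.mass, e.sequence, e.modifications))
        self.entries = entries
        self.masses = np.array([e.mass for e in entries], dtype=float)

    @classmethod
    def build(cls, db: SearchDatabase, params: SearchParams) -> "PeptideIndex":
        provenance: dict[str, set[str]] = {}
        has_target: dict[str, bool] = {}
        for rec in db.all_records:
            for cand in digest(rec.sequence, params):
                provenance.setdefault(cand.sequence, set()).add(rec.protein_id)
                if not rec.is_decoy:
                    has_target[cand.sequence] = True
        entries: list[_Entry] = []
        n_skipped = 0
        for seq, prots in provenance.items():
            if "X" in seq:
                n_skipped += 1
                continue
            base = peptide_mass(seq, fixed_mods=params.fixed_mods)
            prot_fs = frozenset(prots)
            target = has_target.get(seq, False)
            entries.append(_Entry(seq, (), base, prot_fs, target))
            for mods in _variable_mod_combos(seq, params):
                entries.append(
                    _Entry(
                        seq,
                        mods,
                        base + sum(d for _, d in mods),
                        prot_fs,
                        target,
                    )
                )
        if n_skipped:
            logger.info("skipped %d peptides containing X", n_skipped)
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def candidates_in_window(
        self, neutral_mass: float, params: SearchParams
    ) -> list[int]:
        """Indices of entries within the ppm window around the observed
        neutral mass for some isotope error k in the configured range."""
        out: set[int] = set()
        k0, k1 = params.isotope_error_range
        for k in range(k0, k1 + 1):
            m0 = neutral_mass - k * ISOTOPE_SPACING
            tol = params.precursor_tol_ppm * m0 / 1e6
            lo = int(np.searchsorted(self.masses, m0 - tol, side="left"))
            hi = int(np.searchsorted(self.masses, m0 + tol, side="right"))
            out.update(range(lo, hi))
        return sorted(out)


def _variable_mod_combos(
    seq: str, params: SearchParams
) -> list[tuple[tuple[int, float], ...]]:
    sites: list[tuple[int, float]] = []
    for residue, delta in params.var_mods:
        sites.extend((i + 1, delta) for i, aa in enumerate(seq) if aa == residue)
    sites.sort()
    combos: list[tuple[tuple[int, float], ...]] = []
    for k in range(1, min(params.max_var_mods, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            combos.append(combo)
            if len(combos) >= _MAX_VARIANTS_PER_PEPTIDE:
                return combos
    return combos


# ---------------------------------------------------------------------------
# Scoring


def fragment_mzs(
    sequence: str,
    modifications: Iterable[tuple[int, float]] = (),
    fixed_mods: Iterable[tuple[str, float]] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Singly charged b- and y-ion m/z ladders (lengths len-1 each)."""
    residues = np.array([MONO_RESIDUE[aa] for aa in sequence], dtype=float)
    for residue, delta in fixed_mods:
        for i, aa in enumerate(sequence):
            if aa == residue:
                residues[i] += delta
    for pos, delta in modifications:
        residues[pos - 1] += delta
    prefix = np.cumsum(residues)
    total = prefix[-1]
    b = prefix[:-1] + PROTON
    y = total - prefix[:-1] + WATER + PROTON
    return b, y


def _count_matches(
    theo: np.ndarray, mz: np.ndarray, intensity: np.ndarray, tol_ppm: float
) -> tuple[int, float]:
    if theo.size == 0 or mz.size == 0:
        return 0, 0.0
    idx = np.searchsorted(mz, theo)
    left = np.clip(idx - 1, 0, mz.size - 1)
    right = np.clip(idx, 0, mz.size - 1)
    d_left = np.abs(mz[left] - theo)
    d_right = np.abs(mz[right] - theo)
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    hit = dist <= tol_ppm * theo / 1e6
    return int(hit.sum()), float(intensity[nearest[hit]].sum())


def score_candidate(
    spectrum, sequence: str, modifications, params: SearchParams
) -> float:
    """Hyperscore-style match score for one candidate against a spectrum."""
    b, y = fragment_mzs(sequence, modifications, params.fixed_mods)
    nb, ib = _count_matches(b, spectrum.mz, spectrum.intensity, params.fragment_tol_ppm)
    ny, iy = _count_matches(y, spectrum.mz, spectrum.intensity, params.fragment_tol_ppm)
    return math.lgamma(nb + 1) + math.lgamma(ny + 1) + math.log1p(ib + iy)


def match_spectrum(
    spectrum,
    index: PeptideIndex,
    params: SearchParams,
) -> PSM | None:
    """Best-scoring candidate for one spectrum, or None.

    Spectra with fewer than ``params.min_peaks`` peaks are skipped. Ties
    are broken deterministically: lexicographically smaller peptide
    string first, then target before decoy.
    """
    if spectrum.n_peaks < params.min_peaks:
        logger.debug("spectrum %s skipped: %d peaks", spectrum.spectrum_id, spectrum.n_peaks)
        return None
    if not params.charge_range[0] <= spectrum.charge <= params.charge_range[1]:
        return None
    cand_idx = index.candidates_in_window(spectrum.neutral_mass, params)
    best_key: tuple[float, str, bool] | None = None
    best_entry: _Entry | None = None
    for i in cand_idx:
        entry = index.entries[i]
        s = score_candidate(spectrum, entry.sequence, entry.modifications, params)
        key = (-s, entry.sequence, not entry.has_target)
        if best_key is None or key < best_key:
            best_key, best_entry = key, entry
    if best_entry is None:
        return None
    return PSM(
        spectrum_id=spectrum.spectrum_id,
        peptide=best_entry.sequence,
        score=-best_key[0],
        is_decoy=not best_entry.has_target,
        protein_ids=best_entry.protein_ids,
        modifications=best_entry.modifications,
    )


def search(
    spectra: Sequence,
    db: SearchDatabase,
    params: SearchParams,
    registry: Mapping[str, str] | None = None,
) -> list[PSM]:
    """Search every spectrum against a database; one best PSM per spectrum.

    ``registry`` maps protein_id -> genome_id over the pre-dedup record
    set; together with the database's dedup_map it credits every genome
    carrying an identical collapsed sequence.
    """
    index = PeptideIndex.build(db, params)
    logger.info("peptide index: %d entries", len(index))
    if registry is None:
        registry = {r.protein_id: r.genome_id for r in db.all_records}
    psms: list[PSM] = []
    for spec in spectra:
        psm = match_spectrum(spec, index, params)
        if psm is None:
            continue
        psm.genome_ids = frozenset(
            expand_protein_genomes(psm.protein_ids, registry, db.dedup_map)
        )
        psms.append(psm)
    return psms


# ---------------------------------------------------------------------------
# External PSM tables

_REQUIRED_PSM_COLUMNS = ("spectrum_id", "peptide", "score", "protein_ids")


def parse_external_psms(
    path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[PSM]:
    """Read a PSM TSV produced by an external engine.

    Columns: spectrum_id, peptide, score, protein_ids (semicolon
    separated). A PSM is a decoy match iff every source protein carries
    the decoy prefix; the best-per-spectrum reduction is applied with the
    same tie-break as the built-in engine.
    """
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str})
    for col in _REQUIRED_PSM_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"PSM table {path}: missing required column {col!r}")
    psms: list[PSM] = []
    for row in df.itertuples(index=False):
        prots = frozenset(p for p in str(row.protein_ids).split(";") if p)
        psms.append(
            PSM(
                spectrum_id=str(row.spectrum_id),
                peptide=str(row.peptide),
                score=float(row.score),
                is_decoy=bool(prots) and all(p.startswith(decoy_prefix) for p in prots),
                protein_ids=prots,
            )
        )
    return best_per_spectrum(psms)


def best_per_spectrum(psms: Iterable[PSM]) -> list[PSM]:
    """Keep the best PSM per spectrum (score, then peptide string, then
    target before decoy), in first-seen spectrum order."""
    best: dict[str, PSM] = {}
    for psm in psms:
        cur = best.get(psm.spectrum_id)
        if cur is None or (-psm.score, psm.peptide, psm.is_decoy) < (
            -cur.score,
            cur.peptide,
            cur.is_decoy,
        ):
            best[psm.spectrum_id] = psm
    return list(best.values())


def write_psms(psms: Sequence[PSM], path: str | Path, extra: Mapping[str, Sequence] | None = None) -> None:
    """Write PSMs as a TSV (the same dialect parse_external_psms reads)."""
    df = psms_to_frame(psms)
    if extra:
        for col, values in extra.items():
            df[col] = values
    df.to_csv(path, sep="\t", index=False)


def psms_to_frame(psms: Sequence[PSM]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "score": [p.score for p in psms],
            "protein_ids": [";".join(sorted(p.protein_ids)) for p in psms],
            "genome_ids": [";".join(sorted(p.genome_ids)) for p in psms],
            "is_decoy": [p.is_decoy for p in psms],
        }
    )
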