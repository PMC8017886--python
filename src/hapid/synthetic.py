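"""Seeded synthetic communities and spectra with known ground truth.

Emulates a defined mixed-culture proteome sample: a handful of genomes
with a specified abundance vector, a designated high-abundance protein
(HAP) subset per genome expressed above the background, MS/MS spectra
generated from tryptic peptides with abundance-proportional sampling,
Gaussian ppm-scale m/z noise, lognormal peak intensities and a stated
fraction of unmatchable noise spectra. Every choice is driven by one
seed so runs are reproducible byte for byte.

Optionally a fraction of each genome's proteins is drawn from shared
protein families (a common ancestor mutated per genome), giving nested
databases the cross-genome near-identical peptides real collections
have; this is what makes small-versus-large database consistency
experiments informative. Off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import PROTON
from .search_engine import SearchParams, digest, fragment_mzs, peptide_mass
from .sequence_db import ProteinRecord
from .spectra import SpectrumRecord, write_mgf

_AA = "ACDEFGHIKLMNPQRSTVWY"
# uniform residue background with K/R boosted so every protein digests
# into usable tryptic peptides
_AA_WEIGHTS = np.array(
    [1.0 if aa not in "KR" else 2.5 for aa in _AA], dtype=float
)
_AA_WEIGHTS /= _AA_WEIGHTS.sum()

#: Abundance skew mirroring a defined eight-member gut community where
#: the five most abundant members carry >= 99% of the identifiable signal
#: and one member is essentially undetectable.
SIHUMI_LIKE_ABUNDANCE = (0.40, 0.25, 0.16, 0.11, 0.07, 0.006, 0.003, 0.001)


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community."""

    n_genomes: int = 8
    proteins_per_genome: int = 20
    haps_per_genome: int = 3
    abundance: tuple[float, ...] | None = None  # defaults to the skewed 8-member vector
    hap_expression_boost: float = 5.0
    noise_spectrum_fraction: float = 0.2
    mz_noise_ppm: float = 5.0
    protein_length: tuple[int, int] = (80, 400)
    homologous_fraction: float = 0.0
    homolog_mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance is None:
            if self.n_genomes == 8:
                self.abundance = SIHUMI_LIKE_ABUNDANCE
            else:
                # geometric decay, normalized
                w = 0.6 ** np.arange(self.n_genomes)
                self.abundance = tuple(w / w.sum())
        self.abundance = tuple(float(a) for a in self.abundance)
        if len(self.abundance) != self.n_genomes:
            raise ValueError(
                f"abundance vector has {len(self.abundance)} entries "
                f"for {self.n_genomes} genomes"
            )
        if abs(sum(self.abundance) - 1.0) > 1e-9:
            raise ValueError("abundance vector must sum to 1")
        if self.haps_per_genome > self.proteins_per_genome:
            raise ValueError("haps_per_genome exceeds proteins_per_genome")
        if not 0 <= self.noise_spectrum_fraction < 1:
            raise ValueError("noise_spectrum_fraction must be in [0, 1)")
        if self.hap_expression_boost < 1:
            raise ValueError("hap_expression_boost must be >= 1")


@dataclass
class CommunityTruth:
    """Generated community with its ground truth."""

    spec: CommunitySpec
    records: list[ProteinRecord]
    taxonomy: dict[str, dict[str, str]]
    abundance: dict[str, float]
    expression_weight: dict[str, float]  # protein_id -> sampling weight

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.abundance)

    def abundance_ranked_genomes(self) -> list[str]:
        return [
            g for g, _ in sorted(
                self.abundance.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]


_RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AA), size=length, p=_AA_WEIGHTS)
    return "".join(_AA[i] for i in idx)


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AA[int(rng.integers(len(_AA)))]
    return "".join(out)


def simulate_community(spec: CommunitySpec) -> CommunityTruth:
    """Generate proteins, HAP flags, taxonomy and expression weights.

    Protein lengths are uniform over ``spec.protein_length``; the first
    ``haps_per_genome`` proteins of each genome are the HAPs and carry
    ribosomal-protein / elongation-factor annotations. The per-protein
    expression weight is the genome abundance times the HAP boost. At
    least two genomes share a taxonomic order so rank roll-ups are
    exercised.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    taxonomy: dict[str, dict[str, str]] = {}
    abundance: dict[str, float] = {}
    weight: dict[str, float] = {}

    n_hom = int(round(spec.homologous_fraction * spec.proteins_per_genome))
    ancestors = [
        _random_sequence(rng, int(rng.integers(*spec.protein_length, endpoint=True)))
        for _ in range(n_hom)
    ]

    for gi in range(spec.n_genomes):
        gid = f"g{gi + 1:03d}"
        abundance[gid] = spec.abundance[gi]
        # two orders shared among genomes: even genomes one order, odd the other
        order = "Bacteroidales" if gi % 2 == 0 else "Lachnospirales"
        taxonomy[gid] = {
            "domain": "Bacteria",
            "phylum": "Bacteroidota" if gi % 2 == 0 else "Firmicutes",
            "class": "Bacteroidia" if gi % 2 == 0 else "Clostridia",
            "order": order,
            "family": f"family_{gi % 4}",
            "genus": f"genus_{gi}",
            "species": f"species_{gi}",
        }
        for pi in range(spec.proteins_per_genome):
            pid = f"{gid}_p{pi + 1:03d}"
            is_hap = pi < spec.haps_per_genome
            if not is_hap and pi - spec.haps_per_genome < n_hom:
                seq = _mutate(
                    rng, ancestors[pi - spec.haps_per_genome], spec.homolog_mutation_rate
                )
            else:
                seq = _random_sequence(
                    rng, int(rng.integers(*spec.protein_length, endpoint=True))
                )
            if is_hap:
                annotation = (
                    f"50S ribosomal protein L{pi + 1}"
                    if pi % 2 == 0
                    else "elongation factor Tu"
                )
            else:
                annotation = "hypothetical protein"
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=gid,
                    sequence=seq,
                    annotation=annotation,
                    is_hap=is_hap,
                )
            )
            weight[pid] = spec.abundance[gi] * (
                spec.hap_expression_boost if is_hap else 1.0
            )
    return CommunityTruth(
        spec=spec,
        records=records,
        taxonomy=taxonomy,
        abundance=abundance,
        expression_weight=weight,
    )


#: Digestion rule used when sampling true peptides: fully tryptic,
#: trypsin/P, up to 2 missed cleavages, lengths the scorer handles well.
_SAMPLING_PARAMS = SearchParams(
    semi_tryptic=False,
    missed_cleavages_max=2,
    min_peptide_length=7,
    max_peptide_length=30,
)


def simulate_spectra(
    truth: CommunityTruth,
    n_spectra: int,
    seed: int | None = None,
) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """Sample spectra from the community's tryptic peptides.

    Each true spectrum picks a protein proportionally to its expression
    weight and one of its tryptic peptides uniformly, then emits the
    singly charged b/y ladder with Normal(0, ppm) m/z perturbation and
    lognormal intensities; the precursor sits at the true peptide mass
    (charge 2) with the same ppm-scale noise. A
    ``noise_spectrum_fraction`` share of spectra carries random peaks
    and precursors matching nothing. Returns the spectra and a
    ground-truth table (spectrum_id, peptide, protein_id, genome_id,
    is_noise).
    """
    if n_spectra <= 0:
        raise ValueError("n_spectra must be positive")
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    peptides_by_protein: dict[str, list[str]] = {}
    for rec in truth.records:
        peps = [c.sequence for c in digest(rec.sequence, _SAMPLING_PARAMS)]
        if peps:
            peptides_by_protein[rec.protein_id] = sorted(peps)
    protein_ids = sorted(peptides_by_protein)
    weights = np.array([truth.expression_weight[p] for p in protein_ids])
    weights = weights / weights.sum()
    genome_of = {r.protein_id: r.genome_id for r in truth.records}

    n_noise = int(round(spec.noise_spectrum_fraction * n_spectra))
    is_noise = np.zeros(n_spectra, dtype=bool)
    if n_noise:
        is_noise[rng.choice(n_spectra, size=n_noise, replace=False)] = True

    spectra: list[SpectrumRecord] = []
    gt_rows: list[dict] = []
    fixed = _SAMPLING_PARAMS.fixed_mods
    for i in range(n_spectra):
        sid = f"scan_{i + 1:05d}"
        if is_noise[i]:
            n_peaks = int(rng.integers(25, 60))
            mz = np.sort(rng.uniform(200.0, 1500.0, size=n_peaks))
            inten = rng.lognormal(3.0, 1.0, size=n_peaks)
            prec = float(rng.uniform(400.0, 1200.0))
            spectra.append(SpectrumRecord(sid, prec, 2, mz, inten))
            gt_rows.append(
                {"spectrum_id": sid, "peptide": "", "protein_id": "",
                 "genome_id": "", "is_noise": True}
            )
            continue
        pid = protein_ids[int(rng.choice(len(protein_ids), p=weights))]
        peps = peptides_by_protein[pid]
        pep = peps[int(rng.integers(len(peps)))]
        b, y = fragment_mzs(pep, fixed_mods=fixed)
        mz = np.concatenate([b, y])
        mz = mz + rng.normal(0.0, spec.mz_noise_ppm * mz / 1e6)
        inten = rng.lognormal(3.0, 1.0, size=mz.size)
        order = np.argsort(mz)
        mass = peptide_mass(pep, fixed_mods=fixed)
        prec = (mass + 2 * PROTON) / 2
        prec += rng.normal(0.0, spec.mz_noise_ppm * prec / 1e6)
        spectra.append(SpectrumRecord(sid, float(prec), 2, mz[order], inten[order]))
        gt_rows.append(
            {"spectrum_id": sid, "peptide": pep, "protein_id": pid,
             "genome_id": genome_of[pid], "is_noise": False}
        )
    return spectra, pd.DataFrame(gt_rows)


def write_community(
    truth: CommunityTruth,
    spectra: list[SpectrumRecord],
    ground_truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, MGF, taxonomy TSV, HAP-flag TSV and ground-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "genome_map": out / "genome_map.tsv",
        "mgf": out / "spectra.mgf",
        "taxonomy": out / "taxonomy.tsv",
        "hap_flags": out / "hap_flags.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for r in truth.records:
            fh.write(f">{r.protein_id} {r.annotation}\n{r.sequence}\n")
    with open(paths["genome_map"], "w") as fh:
        fh.write("protein_id\tgenome_id\n")
        for r in truth.records:
            fh.write(f"{r.protein_id}\t{r.genome_id}\n")
    write_mgf(spectra, paths["mgf"])
    with open(paths["taxonomy"], "w") as fh:
        fh.write("genome_id\tlineage\n")
        for gid in sorted(truth.taxonomy):
            lineage = ";".join(truth.taxonomy[gid][r] for r in _RANK_NAMES)
            fh.write(f"{gid}\t{lineage}\n")
    with open(paths["hap_flags"], "w") as fh:
        fh.write("protein_id\tis_hap\n")
        for r in truth.records:
            fh.write(f"{r.protein_id}\t{int(r.is_hap)}\n")
    ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
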