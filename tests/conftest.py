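"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (brute-force
substring enumeration for digestion, one-line greedy and exhaustive
subset search for set cover) used to validate the package's optimized
code paths.
"""

from __future__ import annotations

import itertools

import pytest

from hapid import (
    CommunitySpec,
    ProteinRecord,
    run_two_step,
    simulate_community,
    simulate_spectra,
)


# ---------------------------------------------------------------------------
# Oracles


def brute_force_digest(
    sequence: str,
    trypsin_p: bool,
    missed_max: int,
    semi: bool,
    min_len: int,
    max_len: int,
) -> set[str]:
    """Every substring tested directly against the cleavage predicate."""

    def cuts_after(i: int) -> bool:
        return sequence[i] in "KR" and (
            trypsin_p or (i + 1 < len(sequence) and sequence[i + 1] != "P")
        )

    n = len(sequence)
    out: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not min_len <= j - i <= max_len:
                continue
            nt = i == 0 or cuts_after(i - 1)
            ct = j == n or cuts_after(j - 1)
            missed = sum(1 for k in range(i, j - 1) if cuts_after(k))
            if missed > missed_max:
                continue
            if (nt and ct) or (semi and (nt or ct)):
                out.add(sequence[i:j])
    return out


def oracle_greedy_cover(inc: dict[str, set[str]], threshold: float) -> list[str]:
    """Independent one-line-per-step greedy cover."""
    uncovered = set(inc)
    n = len(inc)
    order: list[str] = []
    while (n - len(uncovered)) / n < threshold:
        gains = {}
        for sid in uncovered:
            for g in inc[sid]:
                gains[g] = gains.get(g, 0) + 1
        if not gains:
            break
        best = min(gains, key=lambda g: (-gains[g], g))
        order.append(best)
        uncovered = {s for s in uncovered if best not in inc[s]}
    return order


def exhaustive_min_cover(inc: dict[str, set[str]]) -> int:
    """Size of a true minimum cover by exhaustive subset search."""
    genomes = sorted({g for gs in inc.values() for g in gs})
    spectra = [gs for gs in inc.values()]
    for k in range(1, len(genomes) + 1):
        for combo in itertools.combinations(genomes, k):
            chosen = set(combo)
            if all(gs & chosen for gs in spectra):
                return k
    return len(genomes)


# ---------------------------------------------------------------------------
# Fixtures


def make_records(*specs: tuple[str, str, str, bool]) -> list[ProteinRecord]:
    """Helper: (protein_id, genome_id, sequence, is_hap) tuples."""
    return [
        ProteinRecord(pid, gid, seq, is_hap=hap) for pid, gid, seq, hap in specs
    ]


@pytest.fixture(scope="session")
def sihumi():
    """An eight-genome skewed community with 2000 spectra and its full
    two-step run: the defined-community analogue used by several tests."""
    truth = simulate_community(CommunitySpec(seed=101))
    spectra, ground_truth = simulate_spectra(truth, 2000)
    result = run_two_step(spectra, truth.records)
    return truth, spectra, ground_truth, result
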