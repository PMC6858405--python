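"""Nucleotide diversity at synonymous and non-synonymous sites (piN/piS).

Nei-Gojobori (1986) proportion counting on codon alignments: every codon
contributes fractional synonymous/non-synonymous site counts (the fraction of
its nine single-base changes that preserve the amino acid), pairwise
differences are classified by averaging over all equal-weight mutational
pathways, and per-site diversities are averaged over all unordered sequence
pairs.  Changes to or through stop codons are counted as non-synonymous.  No
multiple-hit correction is applied; within-species diversities are small.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonAlignment",
    "DiversityResult",
    "load_alignment",
    "count_sites",
    "pairwise_differences",
    "pi_n_pi_s",
]

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)
_BASES = "ACGT"


@dataclass
class DiversityResult:
    pi_n: float
    pi_s: float
    n_pairs: int

    @property
    def ratio(self) -> float | None:
        """piN/piS, or None when piS is zero (undefined, not 0)."""
        if self.pi_s > 0:
            return self.pi_n / self.pi_s
        return None


@dataclass
class CodonAlignment:
    """Equal-length in-frame nucleotide sequences ('-' gaps allowed)."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned (equal length)")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for sid, seq in zip(self.ids, self.sequences):
            for j in range(0, length, 3):
                codon = seq[j : j + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon {codon} in {sid} at {j}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, seq_index: int, codon_index: int) -> str:
        return self.sequences[seq_index][3 * codon_index : 3 * codon_index + 3]


def load_alignment(path) -> CodonAlignment:
    """Read an in-frame codon alignment from FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return CodonAlignment([r.id for r in records], [str(r.seq) for r in records])


def _is_clean(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


def count_sites(codon: str) -> tuple[float, float]:
    """(non-synonymous, synonymous) site counts of a sense codon; sums to 3.

    Each position contributes the fraction of its three possible base changes
    that are synonymous; changes producing a stop are non-synonymous.
    """
    codon = codon.upper()
    if not _is_clean(codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def _step_is_synonymous(before: str, after: str) -> bool:
    if before in STOP_CODONS or after in STOP_CODONS:
        return False  # stop-involving steps count as non-synonymous
    return CODON_TO_AA[before] == CODON_TO_AA[after]


def pairwise_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(non-synonymous, synonymous) differences between two sense codons.

    Multi-hit codons are averaged over all orderings of the differing
    positions with equal weight.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        syn_path = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _step_is_synonymous(current, nxt):
                syn_path += 1.0
            current = nxt
        syn_total += syn_path
        n_paths += 1
    syn = syn_total / n_paths
    return len(diff_pos) - syn, syn


def pi_n_pi_s(alignment: CodonAlignment) -> DiversityResult:
    """Average pairwise per-site diversity at non-synonymous and synonymous sites.

    For each unordered pair, codon columns where either sequence has a gap,
    an ambiguity code or a stop codon are skipped; site counts are the mean of
    the two sequences' counts over the shared codons.  Per-pair piN and piS
    are then averaged across pairs.
    """
    n = len(alignment.sequences)
    pi_n_vals, pi_s_vals = [], []
    for a in range(n):
        for b in range(a + 1, n):
            sites_n = sites_s = 0.0
            diffs_n = diffs_s = 0.0
            for c in range(alignment.n_codons):
                ca, cb = alignment.codon(a, c), alignment.codon(b, c)
                if not (_is_clean(ca) and _is_clean(cb)):
                    continue
                if ca in STOP_CODONS or cb in STOP_CODONS:
                    continue
                na, sa = count_sites(ca)
                nb, sb = count_sites(cb)
                sites_n += (na + nb) / 2.0
                sites_s += (sa + sb) / 2.0
                dn, ds = pairwise_differences(ca, cb)
                diffs_n += dn
                diffs_s += ds
            pi_n_vals.append(diffs_n / sites_n if sites_n > 0 else 0.0)
            pi_s_vals.append(diffs_s / sites_s if sites_s > 0 else 0.0)
    return DiversityResult(
        pi_n=float(np.mean(pi_n_vals)),
        pi_s=float(np.mean(pi_s_vals)),
        n_pairs=len(pi_n_vals),
    )
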