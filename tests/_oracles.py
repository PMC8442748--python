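"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes an expectation by a route independent of the library
code path it checks: exhaustive enumeration for region maximality and codon
effects, scipy for the chi-square law.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def brute_force_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """All maximal window-index intervals [i, j] with every window above
    threshold, found by testing every interval for validity and maximality."""
    n = above.size
    runs = []
    for i in range(n):
        for j in range(i, n):
            if not all(above[i : j + 1]):
                continue
            left_max = i == 0 or not above[i - 1]
            right_max = j == n - 1 or not above[j + 1]
            if left_max and right_max:
                runs.append((i, j))
    return runs


def codon_effect_oracle(ref: str, alt: str) -> str:
    """Effect of a codon substitution by direct Biopython translation."""
    aa_ref = str(Seq(ref).translate())
    aa_alt = str(Seq(alt).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    return "non_synonymous"


def all_single_base_codon_changes():
    """All 64 x 9 = 576 (ref_codon, alt_codon) single-base substitutions."""
    for ref in map("".join, itertools.product(BASES, repeat=3)):
        for i in range(3):
            for b in BASES:
                if b != ref[i]:
                    yield ref, ref[:i] + b + ref[i + 1 :]
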