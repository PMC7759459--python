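"""Poisson model of chance-invariant alignment columns.

Under a homogeneous Poisson substitution process, a site accumulating
substitutions at total tree branch length L (substitutions per site) is
unchanged in every lineage with probability e^(-L). Multiplying by
genome size G gives the expected number of positions identical across
all aligned species by chance alone — the false-positive floor for
detecting evolutionary constraint.
"""

from __future__ import annotations

import math

import numpy as np


def fraction_invariant(branch_length: float | np.ndarray) -> float | np.ndarray:
    """P(zero substitutions at a site) = e^(-L).

    Accepts a scalar total branch length or a per-site rate vector, in
    which case the mean of e^(-L_i) over sites is returned (rate
    heterogeneity across sites).
    """
    L = np.asarray(branch_length, dtype=float)
    if np.any(L < 0):
        raise ValueError("branch length must be >= 0")
    frac = np.exp(-L)
    if frac.ndim == 0:
        return float(frac)
    return float(frac.mean())


def expected_invariant_sites(genome_size: float, branch_length: float | np.ndarray) -> float:
    """Expected chance-invariant positions: G * e^(-L)."""
    if genome_size < 0:
        raise ValueError("genome size must be >= 0")
    return genome_size * fraction_invariant(branch_length)


def expected_invariant_sites_rounded(genome_size: float, branch_length: float) -> int:
    """`expected_invariant_sites` rounded to the nearest integer, for reporting."""
    return round(expected_invariant_sites(genome_size, branch_length))


def required_branch_length(genome_size: float, target_sites: float) -> float:
    """Total branch length at which only `target_sites` positions remain
    invariant by chance: L = ln(G / target).

    Inverse of :func:`expected_invariant_sites`; round-trips to within
    1e-6 relative.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    if not (0 < target_sites <= genome_size):
        raise ValueError("target_sites must lie in (0, genome_size]")
    return math.log(genome_size / target_sites)
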