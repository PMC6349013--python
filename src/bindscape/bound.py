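"""Bound-state classification.

A ligand copy is *bound* when its center of mass lies within 5 Å of any
protein heavy atom — a distance comparable to the inhibitor radius, so the
criterion marks genuine surface contact.  It is in the *effective* bound state
when it is bound AND its RMSD to the native pocket pose is below 15 Å, the
approximate pocket diameter: effectively-bound snapshots are the ones sitting
inside the target pocket rather than elsewhere on the surface.

A whole trajectory counts as *successful* (it captured a binding event) when
the ligand ends up fluctuating stably inside the pocket: every RMSD in the
final stretch of the series stays below the pocket-scale cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError

__all__ = [
    "BindingCall",
    "BOUND_CUTOFF",
    "EFFECTIVE_RMSD_CUTOFF",
    "is_bound",
    "is_effective",
    "classify_trajectory",
    "effective_binding_percent",
]

BOUND_CUTOFF = 5.0  # Å, COM-to-nearest-heavy-atom
EFFECTIVE_RMSD_CUTOFF = 15.0  # Å, ~pocket diameter


@dataclass
class BindingCall:
    """Per-snapshot classification: bound flag, nearest-atom distance,
    effective flag, and the RMSD used (if any)."""

    bound: bool
    min_dist: float
    effective: bool = False
    rmsd: float | None = None


def is_bound(com, protein_heavy_atoms, cutoff: float = BOUND_CUTOFF) -> BindingCall:
    """Classify one COM against the protein heavy-atom cloud.

    Bound iff the minimum Euclidean distance is strictly below ``cutoff``.
    A KD-tree makes the query O(log n); the brute-force scan is the test
    oracle.
    """
    atoms = np.asarray(protein_heavy_atoms, dtype=float)
    if atoms.size == 0:
        raise InputError("empty protein atom set")
    atoms = atoms.reshape(-1, 3)
    tree = cKDTree(atoms)
    min_dist, _ = tree.query(np.asarray(com, dtype=float))
    min_dist = float(min_dist)
    return BindingCall(bound=min_dist < cutoff, min_dist=min_dist)


def bind_calls(
    coms, protein_heavy_atoms, cutoff: float = BOUND_CUTOFF
) -> list[BindingCall]:
    """Vectorized :func:`is_bound` over many COMs (one shared KD-tree)."""
    atoms = np.asarray(protein_heavy_atoms, dtype=float).reshape(-1, 3)
    if atoms.size == 0:
        raise InputError("empty protein atom set")
    dists, _ = cKDTree(atoms).query(np.atleast_2d(np.asarray(coms, dtype=float)))
    return [BindingCall(bound=float(d) < cutoff, min_dist=float(d)) for d in dists]


def is_effective(
    call: BindingCall, rmsd: float, rmsd_cutoff: float = EFFECTIVE_RMSD_CUTOFF
) -> bool:
    """Effective ⇔ bound AND RMSD to the native pose strictly below cutoff.

    Updates ``call`` in place (effective flag and rmsd) and returns the flag.
    """
    effective = bool(call.bound and rmsd < rmsd_cutoff)
    call.effective = effective
    call.rmsd = float(rmsd)
    return effective


def classify_trajectory(
    rmsd_series,
    cutoff: float = EFFECTIVE_RMSD_CUTOFF,
    tail_fraction: float = 0.2,
) -> bool:
    """Successful ⇔ every RMSD in the final ``tail_fraction`` of the
    time-ordered series is strictly below ``cutoff``.

    Requiring the whole tail (not just the last frame) below the pocket scale
    encodes the stability requirement: a ligand that dips into the pocket and
    leaves again did not bind.
    """
    series = np.asarray(rmsd_series, dtype=float)
    if series.ndim != 1 or len(series) < 10:
        raise InputError("rmsd series must be 1-D with at least 10 samples")
    n_tail = max(1, int(np.ceil(tail_fraction * len(series))))
    return bool(np.all(series[-n_tail:] < cutoff))


def effective_binding_percent(calls: list[BindingCall]) -> float:
    """Percentage of effective calls among all snapshot-ligand observations,
    reported at two decimals (each stored snapshot of each ligand copy counts
    once)."""
    if not calls:
        raise InputError("empty call set")
    pct = 100.0 * sum(c.effective for c in calls) / len(calls)
    return float(round(pct, 2))
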