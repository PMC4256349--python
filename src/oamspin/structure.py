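"""Spin-label site geometry: model distances, measurability, reconciliation.

Spin labels attached at engineered or native cysteines (e.g. Cys352 and
Cys700 of the OAM dimer) define a network of inter-label distances that can
be predicted from a structural model and compared with distances measured
by PELDOR.  Whether a given distance is measurable depends on the
acquisition window: the dipolar oscillation must complete a minimum
fraction of a cycle within the observed evolution time, and its frequency
must lie below the Nyquist limit of the sampling step.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .dipolar import GE_FREE, perpendicular_frequency
from .errors import InvalidParameterError, SelectionError
from .peldor import PeldorTiming

__all__ = [
    "SiteKind",
    "LabelSite",
    "DistancePrediction",
    "ReconciliationReport",
    "read_sites",
    "pairwise_distances",
    "is_measurable",
    "annotate_measurability",
    "reconcile",
]


class SiteKind(enum.Enum):
    NITROXIDE_LABEL = "nitroxide_label"
    COBALT_CENTER = "cobalt_center"
    OTHER = "other"


@dataclass(frozen=True)
class LabelSite:
    """A named spin-bearing position in a structural model.

    Coordinates are in Å, copied verbatim from the coordinate file;
    residue numbering follows the 1-based PDB convention.
    """

    name: str
    chain: str
    residue_number: int
    position: tuple[float, float, float]
    kind: SiteKind = SiteKind.NITROXIDE_LABEL

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise InvalidParameterError(f"site {self.name} has non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class DistancePrediction:
    """A predicted inter-site distance, optionally annotated with measurability."""

    site_a: LabelSite
    site_b: LabelSite
    r: float  # Å
    measurable: Optional[bool] = None
    note: str = ""

    @property
    def pair_label(self) -> str:
        names = sorted([f"{self.site_a.chain}/{self.site_a.name}",
                        f"{self.site_b.chain}/{self.site_b.name}"])
        return f"{names[0]}–{names[1]}"


@dataclass
class ReconciliationReport:
    """Result of matching measured distance assignments to model predictions."""

    matches: list  # (assignment, prediction, gap_A)
    unmatched_assignments: list
    unmatched_predictions: list  # (prediction, reason)


def read_sites(
    path,
    selection: Sequence[tuple],
    default_atom: str = "SG",
) -> list[LabelSite]:
    """Resolve label sites from a coordinate file in PDB format.

    ``selection`` entries are ``(chain, residue_number, atom_name, kind)``;
    ``atom_name`` may be None to use ``default_atom`` (SG, the cysteine
    thiol sulfur that carries the MTSL label).  Each selector must resolve
    to exactly one atom.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise SelectionError(f"{path} contains no models")
    model = st[0]
    sites: list[LabelSite] = []
    for sel in selection:
        chain_name, resnum, atom_name, kind = (list(sel) + [None] * 4)[:4]
        atom_name = atom_name or default_atom
        kind = SiteKind(kind) if kind else SiteKind.NITROXIDE_LABEL
        chain = model.find_chain(str(chain_name))
        if chain is None:
            raise SelectionError(f"chain {chain_name!r} not found in {path}")
        hits = [
            (res, atom)
            for res in chain
            if res.seqid.num == int(resnum)
            for atom in res
            if atom.name == atom_name
        ]
        if len(hits) != 1:
            raise SelectionError(
                f"selector (chain={chain_name}, residue={resnum}, atom={atom_name}) "
                f"resolved to {len(hits)} atoms in {path}"
            )
        res, atom = hits[0]
        sites.append(
            LabelSite(
                name=f"{res.name}{resnum}",
                chain=str(chain_name),
                residue_number=int(resnum),
                position=(atom.pos.x, atom.pos.y, atom.pos.z),
                kind=kind,
            )
        )
    return sites


def pairwise_distances(sites: Sequence[LabelSite]) -> list[DistancePrediction]:
    """Euclidean distances for all unordered site pairs, Å."""
    preds = []
    for a, b in itertools.combinations(sites, 2):
        preds.append(DistancePrediction(site_a=a, site_b=b, r=float(np.linalg.norm(a.xyz - b.xyz))))
    return preds


def is_measurable(
    r_angstrom: float,
    timing: PeldorTiming,
    min_cycles: float = 0.4,
    g1: float = GE_FREE,
    g2: float = GE_FREE,
) -> tuple[bool, str]:
    """Decide whether a distance is measurable under given acquisition timing.

    A distance is measurable iff its perpendicular dipolar frequency
    completes at least ``min_cycles`` oscillations within the evolution
    window (n_points·dt) and lies below the Nyquist frequency 1/(2·dt).
    Long distances fail the cycle criterion; very short ones the Nyquist
    criterion.
    """
    if not (r_angstrom > 0):
        raise InvalidParameterError(f"distance must be > 0 A, got {r_angstrom}")
    nu = float(perpendicular_frequency(r_angstrom / 10.0, g1, g2))  # MHz
    window_us = timing.window_ns * 1e-3
    cycles = nu * window_us
    nyquist = 1e3 / (2.0 * timing.dt)  # MHz
    if nu > nyquist:
        return False, (
            f"ν⊥ = {nu:.3g} MHz exceeds the Nyquist limit {nyquist:.3g} MHz "
            f"of the {timing.dt} ns sampling step"
        )
    if cycles < min_cycles:
        return False, (
            f"ν⊥ = {nu:.3g} MHz completes only {cycles:.2f} cycles in the "
            f"{timing.window_ns:.0f} ns window (< {min_cycles})"
        )
    return True, (
        f"ν⊥ = {nu:.3g} MHz completes {cycles:.2f} cycles in the window "
        f"and is below Nyquist"
    )


def annotate_measurability(
    predictions: Sequence[DistancePrediction],
    timing: PeldorTiming,
    min_cycles: float = 0.4,
    g1: float = GE_FREE,
    g2: float = GE_FREE,
) -> list[DistancePrediction]:
    """Fill the ``measurable`` flag and rationale of each prediction in place."""
    for p in predictions:
        p.measurable, p.note = is_measurable(p.r, timing, min_cycles, g1, g2)
    return list(predictions)


def reconcile(
    assignments: Sequence,
    predictions: Sequence[DistancePrediction],
    tolerance: float = 5.0,
    spin_pair_kinds: Optional[tuple] = None,
) -> ReconciliationReport:
    """Match measured distance assignments to measurable model predictions.

    Greedy nearest-distance matching: candidate (assignment, prediction)
    pairs within ``tolerance`` Å are taken in order of increasing distance
    gap (ties broken by lexical site names); each assignment and each
    prediction is used at most once.  Predictions flagged non-measurable are
    never matched.  Assignments may be DistanceAssignment objects or plain
    distances in Å.

    ``spin_pair_kinds`` restricts candidates to predictions between sites of
    the given kinds: a Co(II)-pumped experiment measures cobalt-to-label
    distances only, so its assignments must not be matched against
    label–label pairs even when the bare distances happen to agree (pass
    ``(SiteKind.COBALT_CENTER, SiteKind.NITROXIDE_LABEL)``).
    """
    if not (tolerance > 0):
        raise InvalidParameterError(f"tolerance must be > 0 A, got {tolerance}")
    kind_filter = None
    if spin_pair_kinds is not None:
        kind_filter = frozenset(SiteKind(k) for k in spin_pair_kinds)

    def r_of(a) -> float:
        return float(getattr(a, "r_A", a))

    candidates = []
    for i, a in enumerate(assignments):
        for j, p in enumerate(predictions):
            if p.measurable is False:
                continue
            if kind_filter is not None and frozenset(
                (p.site_a.kind, p.site_b.kind)
            ) != kind_filter:
                continue
            gap = abs(r_of(a) - p.r)
            if gap <= tolerance:
                candidates.append((gap, p.pair_label, i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for gap, _, i, j in candidates:
        if i in used_a or j in used_p:
            continue
        used_a.add(i)
        used_p.add(j)
        matches.append((assignments[i], predictions[j], gap))

    unmatched_a = [a for i, a in enumerate(assignments) if i not in used_a]
    unmatched_p = []
    for j, p in enumerate(predictions):
        if j in used_p:
            continue
        if p.measurable is False:
            reason = "not measurable under the given timing"
        elif kind_filter is not None and frozenset(
            (p.site_a.kind, p.site_b.kind)
        ) != kind_filter:
            reason = "site kinds do not match the experiment's spin pair"
        else:
            reason = "no assignment within tolerance"
        unmatched_p.append((p, reason))
    return ReconciliationReport(
        matches=matches,
        unmatched_assignments=unmatched_a,
        unmatched_predictions=unmatched_p,
    )
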