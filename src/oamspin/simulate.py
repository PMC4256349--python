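"""Seeded generators for every input class the analysis pipeline consumes.

Defaults emulate the study conditions of the spin-labeled OAM work:

* PELDOR traces with the reported acquisition timing (148 points in 8-ns
  steps, τ = 200 ns), one or two distance components in the 29–47 Å range,
  a modulation depth that is not known a priori, and a smooth background;
* coupled-assay Michaelis–Menten datasets with kcat in the 0.1–3 s⁻¹ range
  and Km near 180–195 μM over a 0–2500 μM substrate design;
* single-exponential 528-nm stopped-flow transients with observed rates of
  500–1000 s⁻¹ over a 0.25-s window;
* synthetic dimer label-site fixtures embedding the open-state
  (49 Å Cys700–Cys352, 29 Å Cys352–Cys352′, >60 Å remaining pairs) and
  closed-state (Co–label 31/19/17 Å) distance sets.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .dipolar import GE_FREE, perpendicular_frequency, powder_kernel
from .errors import ConfigurationError
from .kinetics import AssayConfig, MMDataset
from .peldor import PeldorTiming, PeldorTrace
from .structure import LabelSite, SiteKind

__all__ = [
    "PeldorSimSpec",
    "MMSimSpec",
    "StoppedFlowSimSpec",
    "simulate_peldor",
    "simulate_mm",
    "simulate_stopped_flow",
    "make_dimer_fixture",
    "OPEN_STATE_DISTANCES",
    "CLOSED_STATE_DISTANCES",
]


@dataclass(frozen=True)
class PeldorSimSpec:
    """Specification of a simulated dipolar evolution trace.

    The echo modulation is

        V(t) = B(t) · [(1 − λ) + λ · Σᵢ wᵢ · K(rᵢ, t)] + ε(t)

    with K the powder-averaged dipolar kernel, λ the modulation depth,
    B(t) = exp(−k_bg·|t − τ|) a smooth background (k_bg in μs⁻¹, 0 = flat)
    and ε Gaussian noise whose SD is ``noise_sd`` × λ.
    """

    components: tuple = ((4.703, 1.0),)  # (r_nm, weight)
    mod_depth: float = 0.3
    background_rate: float = 0.0  # μs⁻¹
    noise_sd: float = 0.0  # fraction of the modulation amplitude λ
    timing: PeldorTiming = field(default_factory=PeldorTiming)
    g1: float = GE_FREE
    g2: float = GE_FREE
    seed: int = 0
    perpendicular_only: bool = False  # collapse θ-average to θ = 90°

    def __post_init__(self) -> None:
        w = sum(w for _, w in self.components)
        if abs(w - 1.0) > 1e-12:
            raise ConfigurationError(f"component weights must sum to 1, got {w}")
        if not (0.0 < self.mod_depth <= 1.0):
            raise ConfigurationError(f"mod_depth must be in (0, 1], got {self.mod_depth}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if any(r <= 0 or w < 0 for r, w in self.components):
            raise ConfigurationError("component distances must be > 0 and weights >= 0")


@dataclass(frozen=True)
class MMSimSpec:
    """Steady-state coupled-assay dataset generator settings.

    Defaults follow the wild-type design: kcat = 2.97 s⁻¹, Km = 189 μM,
    ten substrate points spanning 10–2250 μM and multiplicative Gaussian
    rate noise.  The default grid places a low-concentration block around
    and below Km (which determines Km) and replicates at saturation (which
    determine kcat) — the standard way initial-rate designs split their
    information budget.
    """

    kcat: float = 2.97
    km: float = 189.0  # μM
    s_grid: tuple = (10.0, 100.0, 200.0, 400.0, 1000.0,
                     2250.0, 2250.0, 2250.0, 2250.0, 2250.0)
    noise_cv: float = 0.05
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.kcat > 0 and self.km > 0):
            raise ConfigurationError("kcat and Km must be > 0")
        if self.noise_cv < 0 or self.n_replicates < 1:
            raise ConfigurationError("noise_cv must be >= 0 and n_replicates >= 1")


@dataclass(frozen=True)
class StoppedFlowSimSpec:
    """Stopped-flow 528-nm transient generator settings.

    The absorbance decrease at 528 nm reports Co–C bond homolysis;
    amplitude is therefore negative-going by default
    (A(t) = a0 + ΔA·exp(−kobs·t) with ΔA > 0 decaying toward a0).
    """

    kobs: float = 877.0  # s⁻¹
    window: float = 0.25  # s
    n_points: int = 5000
    amplitude: float = 0.05  # absorbance change magnitude
    a0: float = 0.45  # final (offset) absorbance
    noise_sd: float = 0.0  # fraction of |amplitude|
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.kobs > 0 and self.window > 0):
            raise ConfigurationError("kobs and window must be > 0")
        if self.n_points < 10:
            raise ConfigurationError(f"n_points must be >= 10, got {self.n_points}")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ConfigurationError("noise_sd must be >= 0 and n_replicates >= 1")


def simulate_peldor(spec: PeldorSimSpec) -> PeldorTrace:
    """Generate a dipolar evolution trace from a simulation spec."""
    timing = spec.timing
    t = timing.dt * np.arange(timing.n_points)
    modulation = np.zeros_like(t)
    for r_nm, w in spec.components:
        if spec.perpendicular_only:
            nu = float(perpendicular_frequency(r_nm, spec.g1, spec.g2))
            k = np.cos(2.0 * np.pi * nu * 1e-3 * (t - timing.tau))
        else:
            k = powder_kernel(r_nm, t, timing.tau, spec.g1, spec.g2)
        modulation += w * k
    background = np.exp(-spec.background_rate * np.abs(t - timing.tau) * 1e-3)
    v = background * ((1.0 - spec.mod_depth) + spec.mod_depth * modulation)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd * spec.mod_depth, size=t.shape)
    return PeldorTrace(
        timing=timing,
        t=t,
        v=v,
        provenance=f"simulated (seed={spec.seed}, components={spec.components})",
    )


def simulate_mm(spec: MMSimSpec, config: Optional[AssayConfig] = None) -> list[MMDataset]:
    """Generate replicate Michaelis–Menten datasets, v = kcat·s/(Km+s)·(1+ε)."""
    rng = np.random.default_rng(spec.seed)
    s = np.asarray(spec.s_grid, dtype=float)
    v_true = spec.kcat * s / (spec.km + s)
    datasets = []
    for _ in range(spec.n_replicates):
        eps = rng.normal(0.0, spec.noise_cv, size=s.shape) if spec.noise_cv > 0 else 0.0
        datasets.append(
            MMDataset(s=s.copy(), v=v_true * (1.0 + eps), unit="per_enzyme_s",
                      config=config or AssayConfig())
        )
    return datasets


def simulate_stopped_flow(spec: StoppedFlowSimSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate replicate single-exponential 528-nm transients.

    Returns a list of ``(t_s, A)`` pairs: A(t) = a0 + ΔA·exp(−kobs·t) plus
    Gaussian noise of SD ``noise_sd``·ΔA.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.window, spec.n_points)
    a_true = spec.a0 + spec.amplitude * np.exp(-spec.kobs * t)
    traces = []
    for _ in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd * abs(spec.amplitude), size=t.shape) if spec.noise_sd > 0 else 0.0
        traces.append((t.copy(), a_true + noise))
    return traces


# ---------------------------------------------------------------------------
# Dimer label-site fixtures
#
# Synthetic coordinate embeddings that realise the stated distance sets;
# they are geometric constructions, not crystallographic coordinates.

#: Open (resting-state) distance constraints, Å.
OPEN_STATE_DISTANCES = {
    ("A/CYS700", "A/CYS352"): 49.0,
    ("A/CYS352", "B/CYS352"): 29.0,
}

#: Closed (active-state) Co–label distance constraints, Å.  The two
#: alternative Co positions carry the 19 vs 17 Å readings of the same
#: Co–Cys352 contact.
CLOSED_STATE_DISTANCES = {
    ("A/CO901", "A/CYS352"): 19.0,
    ("A/CO901", "B/CYS352"): 31.0,
    ("A/CO902", "A/CYS352"): 17.0,
    ("A/CO902", "B/CYS352"): 31.0,
}


def _open_coordinates() -> dict:
    # C352 at origin, C352' on x at 29 Å; C700 placed 49 Å from C352 on the
    # far side so that C700–C352' and the symmetry-related C700'–pairs all
    # exceed 60 Å.  C700' is the C2 image (x,y,z) → (29−x, −y, z).
    z700 = math.sqrt(49.0**2 - 30.0**2)  # 38.7427...
    return {
        ("A", 352, "CYS", "SG"): (0.0, 0.0, 0.0),
        ("B", 352, "CYS", "SG"): (29.0, 0.0, 0.0),
        ("A", 700, "CYS", "SG"): (-30.0, 0.0, z700),
        ("B", 700, "CYS", "SG"): (59.0, 0.0, z700),
    }


def _closed_coordinates() -> dict:
    # Co at (x, 0, z) with |Co−C352| = 19 and |Co−C352'| = 31 (and the 17 Å
    # alternative as a second Co position).
    def co(d_same: float, d_other: float) -> tuple:
        x = (d_same**2 - d_other**2 + 29.0**2) / (2.0 * 29.0)
        z = math.sqrt(d_same**2 - x**2)
        return (x, 0.0, z)

    return {
        ("A", 352, "CYS", "SG"): (0.0, 0.0, 0.0),
        ("B", 352, "CYS", "SG"): (29.0, 0.0, 0.0),
        ("A", 901, "CO", "CO"): co(19.0, 31.0),
        ("A", 902, "CO", "CO"): co(17.0, 31.0),
    }


def make_dimer_fixture(
    conformation: str = "open", path: Optional[Path] = None
) -> tuple[list[LabelSite], str]:
    """Build a synthetic dimer label-site fixture and its PDB-format text.

    ``conformation="open"`` embeds the resting-state inter-label distances
    (49 Å Cys700–Cys352 within a monomer, 29 Å Cys352–Cys352′ across the
    dimer, with the remaining Cys pairs beyond 60 Å); ``"closed"`` embeds
    the Co–Cys352 contact distances (19 Å, with a 17 Å alternative Co
    position) and the 31 Å Co–Cys352′ cross-dimer distance.  Coordinates
    are synthetic embeddings honouring these constraints, verified to
    0.01 Å at build time.

    If ``path`` is given the PDB text is also written there.
    """
    if conformation == "open":
        coords, constraints = _open_coordinates(), OPEN_STATE_DISTANCES
    elif conformation == "closed":
        coords, constraints = _closed_coordinates(), CLOSED_STATE_DISTANCES
    else:
        raise ConfigurationError(f"conformation must be 'open' or 'closed', got {conformation!r}")

    sites = []
    for (chain, resnum, resname, atom), xyz in coords.items():
        kind = SiteKind.COBALT_CENTER if resname == "CO" else SiteKind.NITROXIDE_LABEL
        sites.append(
            LabelSite(name=f"{resname}{resnum}", chain=chain, residue_number=resnum,
                      position=xyz, kind=kind)
        )

    # embedding feasibility check: every stated constraint holds by construction
    by_key = {f"{s.chain}/{s.name}": s for s in sites}
    for (ka, kb), d in constraints.items():
        got = float(np.linalg.norm(by_key[ka].xyz - by_key[kb].xyz))
        if abs(got - d) > 0.01:
            raise ConfigurationError(
                f"fixture embedding violates constraint {ka}-{kb}: {got:.3f} != {d}"
            )

    pdb_text = _sites_to_pdb(coords)
    if path is not None:
        Path(path).write_text(pdb_text)
    return sites, pdb_text


def _sites_to_pdb(coords: dict) -> str:
    st = gemmi.Structure()
    st.name = "synthetic dimer label-site fixture"
    model = gemmi.Model("1")
    serial = 1
    for chain_name in sorted({c for (c, *_ ) in coords}):
        chain = gemmi.Chain(chain_name)
        for (c, resnum, resname, atom_name), xyz in coords.items():
            if c != chain_name:
                continue
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if resname == "CO" else "A"
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("Co" if atom_name == "CO" else "S")
            atom.pos = gemmi.Position(*xyz)
            atom.serial = serial
            serial += 1
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
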