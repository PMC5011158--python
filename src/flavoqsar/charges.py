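"""Per-atom property channels that weight the 3D descriptors.

Four channels are computed from the molecular graph alone (coordinates
never enter):

* ``sigma_charge`` — partial equalization of orbital electronegativity
  (PEOE): the iterative σ-charge scheme with electronegativity a quadratic
  polynomial χ(q) = a + b·q + c·q² per atom type and charge transfer along
  each bond damped by (1/2)^k at iteration k.
* ``pi_charge`` — Hückel-type π-charge equalization over each conjugated
  subgraph: diagonalize the Hückel matrix (Coulomb terms α + h·β, resonance
  terms k·β), fill the lowest orbitals, and report (electrons contributed −
  π population) per atom.  Atoms outside conjugated systems carry 0.
* ``total_charge`` — σ + π, summing to the molecular net formal charge.
* ``lp_en`` — residual electronegativity χ(q_converged) of lone-pair
  bearing atoms on the PEOE polynomial scale (eV-like), 0 elsewhere.

The σ scheme uses the classic published polynomial coefficients; the π and
lone-pair parameterizations of the commercial descriptor program are
proprietary, so this module documents its own deterministic variant (Hückel
h/k constants below) and exposes every knob.  Exact numerical parity with
that program is not claimed anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures_io import AROMATIC, Molecule3D

__all__ = [
    "AtomChannels", "ChargeError", "peoe_sigma", "pi_charges",
    "lone_pair_en", "compute_channels", "channels_frame",
]


class ChargeError(ValueError):
    """Unparameterized element or invalid charge-model input."""


# ---------------------------------------------------------------------------
# PEOE σ charges
# ---------------------------------------------------------------------------

# χ(q) = a + b q + c q² [eV-like]; keyed by (element, hybridisation tag).
# Classic published values for H, C, N, O, S, F, Cl, Br, I (+ the common
# P extension).  Hybridisation tags: "sp3", "sp2", "sp" from the maximum
# bond order (aromatic counts as sp2).
PEOE_PARAMS = {
    ("H", "sp3"): (7.17, 0.56, 0.13),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("I", "sp3"): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("S", "sp2"): (10.14, 9.13, 1.38),
    ("P", "sp3"): (8.90, 8.24, 0.96),
}

#: cation electronegativity χ⁺ used to normalize charge flow out of an atom;
#: a + b + c for every atom type except hydrogen, which uses 20.02.
H_CATION_EN = 20.02

_ORDER_VALUE = {1: 1.0, 2: 2.0, 3: 3.0, AROMATIC: 1.5}


def _hybridisation(mol: Molecule3D) -> list:
    """sp/sp2/sp3 tag per atom from incident bond orders."""
    tags = ["sp3"] * mol.n_atoms
    n_double = [0] * mol.n_atoms
    for i, j, order in mol.bonds:
        for a in (i, j):
            if order == 3:
                tags[a] = "sp"
            elif order == 2:
                n_double[a] += 1
                if tags[a] != "sp":
                    tags[a] = "sp2"
            elif order == AROMATIC and tags[a] == "sp3":
                tags[a] = "sp2"
    for a, nd in enumerate(n_double):
        if nd >= 2:  # cumulated double bonds (allene centre)
            tags[a] = "sp"
    return tags


def _peoe_coeffs(mol: Molecule3D):
    tags = _hybridisation(mol)
    abc = np.empty((mol.n_atoms, 3))
    for idx, (sym, _, _) in enumerate(mol.atoms):
        key = (sym, tags[idx])
        if key not in PEOE_PARAMS and (sym, "sp3") in PEOE_PARAMS:
            key = (sym, "sp3")
        if key not in PEOE_PARAMS:
            raise ChargeError(
                f"element {sym!r} (atom {idx}) outside the PEOE parameter set")
        abc[idx] = PEOE_PARAMS[key]
    return abc


def peoe_sigma(mol: Molecule3D, iterations: int = 6,
               damping: float = 0.5) -> np.ndarray:
    """σ partial charges by damped electronegativity equalization.

    Starting from the formal charges, each iteration k evaluates every
    atom's electronegativity χ_i = a_i + b_i q_i + c_i q_i² and moves, along
    each bond, Δq = (χ_hi − χ_lo)/χ⁺_lo · damping^k of positive charge onto
    the less electronegative atom, where χ⁺_lo is the cation
    electronegativity of that atom.  Transfers within one iteration are
    computed from the iteration-start charges, so the result is independent
    of atom ordering.  Total charge is conserved exactly.
    """
    abc = _peoe_coeffs(mol)
    q = mol.formal_charges.astype(float)
    cation_en = abc.sum(axis=1)
    for idx, (sym, _, _) in enumerate(mol.atoms):
        if sym == "H":
            cation_en[idx] = H_CATION_EN
    for k in range(1, iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q ** 2
        factor = damping ** k
        delta = np.zeros_like(q)
        for i, j, _ in mol.bonds:
            if chi[i] == chi[j]:
                continue
            lo, hi = (i, j) if chi[i] < chi[j] else (j, i)
            dq = (chi[hi] - chi[lo]) / cation_en[lo] * factor
            delta[lo] += dq
            delta[hi] -= dq
        q += delta
    return q


def residual_en(mol: Molecule3D, q: np.ndarray) -> np.ndarray:
    """PEOE electronegativity polynomial evaluated at charges ``q``."""
    abc = _peoe_coeffs(mol)
    return abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q ** 2


# ---------------------------------------------------------------------------
# Hückel π charges
# ---------------------------------------------------------------------------

# Coulomb-integral shifts h (units of β) per (element, electrons donated);
# heteroatom values after the standard Hückel parameter compilations.
HUCKEL_H = {
    ("C", 1): 0.00,
    ("N", 1): 0.51,   # pyridine-like
    ("N", 2): 1.37,   # pyrrole/amine donor
    ("O", 1): 0.97,   # carbonyl
    ("O", 2): 2.09,   # ether/furan/hydroxyl donor
    ("S", 1): 0.46,
    ("S", 2): 1.11,   # thiophene-like
    ("F", 2): 2.71,
    ("Cl", 2): 1.48,
    ("Br", 2): 1.50,
    ("I", 2): 1.35,
    ("P", 1): 0.19,
    ("P", 2): 0.75,
}
# Resonance-integral factors k per unordered element pair (class-resolved
# where the compilations distinguish them; geometric-mean fallback below).
HUCKEL_K = {
    frozenset([("C", 1)]): 1.00,
    frozenset([("C", 1), ("N", 1)]): 1.02,
    frozenset([("C", 1), ("N", 2)]): 0.89,
    frozenset([("C", 1), ("O", 1)]): 1.06,
    frozenset([("C", 1), ("O", 2)]): 0.66,
    frozenset([("C", 1), ("S", 1)]): 0.81,
    frozenset([("C", 1), ("S", 2)]): 0.69,
    frozenset([("C", 1), ("F", 2)]): 0.52,
    frozenset([("C", 1), ("Cl", 2)]): 0.62,
    frozenset([("C", 1), ("Br", 2)]): 0.35,
    frozenset([("C", 1), ("I", 2)]): 0.25,
    frozenset([("N", 1)]): 0.85,
    frozenset([("N", 1), ("N", 2)]): 0.85,
    frozenset([("N", 1), ("O", 2)]): 0.80,
    frozenset([("O", 1), ("C", 1)]): 1.06,
}
_K_FALLBACK = 0.80
_DEGENERACY_TOL = 1e-9

# valence electrons for lone-pair counting
_VALENCE_E = {"H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "P": 5, "S": 6,
              "Cl": 7, "Br": 7, "I": 7}


def _bond_order_sums(mol: Molecule3D) -> np.ndarray:
    tot = np.zeros(mol.n_atoms)
    for i, j, order in mol.bonds:
        tot[i] += _ORDER_VALUE[order]
        tot[j] += _ORDER_VALUE[order]
    return tot


def lone_pair_counts(mol: Molecule3D) -> np.ndarray:
    """Integer lone pairs per atom: (valence e⁻ − formal charge − Σ bond
    orders) / 2, floored at 0 (aromatic bonds count 1.5)."""
    bos = _bond_order_sums(mol)
    out = np.zeros(mol.n_atoms, dtype=int)
    for idx, (sym, chg, _) in enumerate(mol.atoms):
        ve = _VALENCE_E.get(sym)
        if ve is None:
            continue
        out[idx] = max(0, int(math.floor((ve - chg - bos[idx]) / 2 + 1e-9)))
    return out


@dataclass
class _PiSystem:
    atoms: list          # atom indices, sorted
    electrons: dict      # atom index -> electrons contributed (0, 1 or 2)
    bonds: list          # (i, j) pairs within the system


def _pi_systems(mol: Molecule3D) -> list:
    """Find conjugated subgraphs and each atom's π-electron contribution.

    π-carrier atoms sit in aromatic or multiple bonds and contribute one
    electron each (two-coordinate aromatic N is pyridine-like; three-
    coordinate aromatic N is a two-electron pyrrole-like donor).  Lone-pair
    atoms bonded to a carrier join as two-electron donors (phenol O, enol
    ether O, aniline N...).  Positive formal charge removes contributed
    electrons (empty p-orbital cations); negative charge adds one.
    """
    n = mol.n_atoms
    adjacency = [[] for _ in range(n)]
    multiple = [False] * n
    aromatic_deg = [0] * n
    for i, j, order in mol.bonds:
        adjacency[i].append((j, order))
        adjacency[j].append((i, order))
        if order in (2, 3):
            multiple[i] = multiple[j] = True
        if order == AROMATIC:
            multiple[i] = multiple[j] = True
            aromatic_deg[i] += 1
            aromatic_deg[j] += 1
    lps = lone_pair_counts(mol)
    heavy_deg = [len(adjacency[i]) for i in range(n)]

    carrier = list(multiple)
    donor = [False] * n
    for idx, (sym, _, _) in enumerate(mol.atoms):
        if carrier[idx] or lps[idx] == 0 or sym == "H":
            continue
        if any(carrier[nb] for nb, _ in adjacency[idx]):
            donor[idx] = True

    member = [c or d for c, d in zip(carrier, donor)]
    seen = [False] * n
    systems = []
    for start in range(n):
        if not member[start] or seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            a = stack.pop()
            comp.append(a)
            for nb, _ in adjacency[a]:
                if member[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        if len(comp) < 2 or not any(carrier[a] for a in comp):
            continue
        electrons = {}
        for a in comp:
            sym, chg, _ = mol.atoms[a]
            if donor[a]:
                base = 2
            elif aromatic_deg[a] > 0 and sym == "N" and heavy_deg[a] >= 3:
                base = 2  # pyrrole-like ring nitrogen
            elif aromatic_deg[a] > 0 and sym in ("O", "S") and heavy_deg[a] >= 2:
                base = 2  # furan/thiophene ring heteroatom
            else:
                base = 1
            electrons[a] = int(np.clip(base - chg, 0, 2))
        bonds = [(i, j) for i, j, order in mol.bonds
                 if i in electrons and j in electrons]
        systems.append(_PiSystem(atoms=sorted(comp), electrons=electrons,
                                 bonds=bonds))
    return systems


def pi_charges(mol: Molecule3D) -> np.ndarray:
    """Hückel π charges; zeros for atoms outside conjugated systems.

    Each conjugated system is solved independently: eigenvectors of the
    Hückel matrix are filled with the system's π electrons from the lowest
    energy up, degenerate shells filled evenly (preserving molecular
    symmetry), and the π charge of an atom is its contributed electrons
    minus its orbital population.  Charges therefore sum to zero over each
    system.
    """
    q = np.zeros(mol.n_atoms)
    for system in _pi_systems(mol):
        idx = {a: m for m, a in enumerate(system.atoms)}
        m = len(system.atoms)
        classes = {}
        for a in system.atoms:
            sym = mol.atoms[a][0]
            classes[a] = (sym, system.electrons[a] if sym != "C" else 1)
        H = np.zeros((m, m))
        for a in system.atoms:
            H[idx[a], idx[a]] = HUCKEL_H.get(classes[a], 1.0)
        for i, j in system.bonds:
            k = HUCKEL_K.get(frozenset([classes[i], classes[j]]), _K_FALLBACK)
            H[idx[i], idx[j]] = H[idx[j], idx[i]] = k
        # energies are α + xβ with β < 0: larger eigenvalue = lower energy
        evals, evecs = np.linalg.eigh(H)
        order = np.argsort(-evals)
        evals, evecs = evals[order], evecs[:, order]
        total_e = float(sum(system.electrons.values()))
        occ = np.zeros(m)
        pos = 0
        remaining = total_e
        while remaining > 1e-12 and pos < m:
            shell = [pos]
            while (shell[-1] + 1 < m
                   and abs(evals[shell[-1] + 1] - evals[pos]) < _DEGENERACY_TOL):
                shell.append(shell[-1] + 1)
            fill = min(remaining, 2.0 * len(shell))
            for s in shell:
                occ[s] = fill / len(shell)
            remaining -= fill
            pos = shell[-1] + 1
        population = (evecs ** 2) @ occ
        for a in system.atoms:
            q[a] = system.electrons[a] - population[idx[a]]
    return q


# ---------------------------------------------------------------------------
# lone-pair electronegativity and the bundled channels
# ---------------------------------------------------------------------------

def lone_pair_en(mol: Molecule3D, sigma: np.ndarray) -> np.ndarray:
    """Residual electronegativity of lone-pair-bearing atoms.

    ``lp_en[i] = a_i + b_i q_i + c_i q_i²`` evaluated at the converged σ
    charge for atoms with at least one lone pair; 0 otherwise.
    """
    lps = lone_pair_counts(mol)
    chi = residual_en(mol, np.asarray(sigma, dtype=float))
    return np.where(lps > 0, chi, 0.0)


@dataclass
class AtomChannels:
    """The four descriptor-weighting channels for one molecule."""

    sigma_charge: np.ndarray
    pi_charge: np.ndarray
    total_charge: np.ndarray
    lp_en: np.ndarray

    def as_dict(self) -> dict:
        return {
            "SigChg": self.sigma_charge,
            "PiChg": self.pi_charge,
            "TotChg": self.total_charge,
            "LpEN": self.lp_en,
        }


def compute_channels(mol: Molecule3D, iterations: int = 6,
                     damping: float = 0.5) -> AtomChannels:
    """Compute all four channels and attach them to ``mol.properties``."""
    sigma = peoe_sigma(mol, iterations=iterations, damping=damping)
    pi = pi_charges(mol)
    channels = AtomChannels(
        sigma_charge=sigma,
        pi_charge=pi,
        total_charge=sigma + pi,
        lp_en=lone_pair_en(mol, sigma),
    )
    mol.properties.update(channels.as_dict())
    return channels


def channels_frame(mols) -> "pandas.DataFrame":
    """Tidy per-atom channel table (id, atom index, element, four channels)."""
    import pandas as pd

    rows = []
    for mol in mols:
        if "SigChg" not in mol.properties:
            compute_channels(mol)
        for i, (sym, _, _) in enumerate(mol.atoms):
            rows.append({
                "molecule_id": mol.id, "atom_index": i, "element": sym,
                "sigma": mol.properties["SigChg"][i],
                "pi": mol.properties["PiChg"][i],
                "total": mol.properties["TotChg"][i],
                "lp_en": mol.properties["LpEN"][i],
            })
    return pd.DataFrame(rows)
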