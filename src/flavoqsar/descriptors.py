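"""Property-weighted 3D molecular descriptors and the descriptor registry.

Two descriptor families are computed from a molecule's 3D geometry and
per-atom property channels:

* **RDF** — property-weighted radial distribution function, the smoothed
  pair-distance histogram ``g(r) = Σ_{i<j} p_i p_j exp(−B (r − r_ij)²)``
  evaluated on 128 bins of width 0.1 Å.  A named bin index k covers the
  r-range [(k−1)·0.1, k·0.1) Å; the kernel is evaluated at the bin midpoint
  by default (configurable to the left edge).  B (Å⁻²) controls the
  smoothing; default 100.
* **3DACorr** — spatial (Moreau–Broto) 3D autocorrelation, the unnormalized
  pair sum ``Σ_{i<j} p_i p_j`` over atom pairs whose distance falls in
  [k, k+1) Å, for k = 1..12.

Both are invariant to rigid rotation/translation and symmetric in atom
order, and scale quadratically when a property channel is scaled.

Names follow ``FAMILY_PROPERTY_INDEX`` (``RDF_PiChg_86``,
``3DACorr_TotChg_9``).  Eight property channels give 8 × 128 = 1024 RDF and
8 × 12 = 96 3DACorr names.  The full registry additionally declares the
8 global, 88 2D-autocorrelation and 36 surface-autocorrelation descriptors
of the original 1252-descriptor space as *names only* (not computable
here — they belong to a surface/topology engine out of scope).
"""

from __future__ import annotations

import numpy as np

from .structures_io import Molecule3D
from .charges import compute_channels, residual_en

__all__ = [
    "RDF_BINS", "RDF_BIN_WIDTH", "ACORR3D_BINS", "PROPERTY_CHANNELS",
    "DescriptorRegistry", "default_registry", "registry_total",
    "bin_range", "rdf", "rdf_profile", "autocorr3d", "autocorr3d_profile",
    "ensure_channels", "compute_all", "descriptor_matrix",
]

RDF_BINS = 128
RDF_BIN_WIDTH = 0.1          # Å
ACORR3D_BINS = 12            # 1 Å bins starting at 1 Å
ACORR3D_BIN_WIDTH = 1.0
DEFAULT_RDF_B = 100.0        # Å⁻², smoothing

#: the eight property channels backing the 1024 RDF / 96 3DACorr names.
#: The first four weight the published model; the last four complete the
#: original program's 8-channel layout (σ/π electronegativities, atomic
#: polarizability, identity).
PROPERTY_CHANNELS = (
    "SigChg", "PiChg", "TotChg", "LpEN", "SigEN", "PiEN", "Polariz", "Ident",
)

# element polarizabilities, Å³ (standard atomic values)
_POLARIZABILITY = {
    "H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
}


class DescriptorRegistry(dict):
    """family name → (properties, bin count, bin width Å, computable)."""

    def total(self) -> int:
        return sum(len(props) * bins if props else bins
                   for props, bins, _, _ in self.values())

    def names(self, family: str) -> list:
        props, bins, _, _ = self[family]
        if not props:
            return [f"{family}_{k}" for k in range(1, bins + 1)]
        return [f"{family}_{p}_{k}" for p in props for k in range(1, bins + 1)]

    def computable_names(self) -> list:
        out = []
        for fam, (_, _, _, computable) in self.items():
            if computable:
                out.extend(self.names(fam))
        return out


def default_registry() -> DescriptorRegistry:
    """The 1252-descriptor space: 8 global + 88 2DACorr + 96 3DACorr +
    1024 RDF + 36 surface autocorrelation."""
    reg = DescriptorRegistry()
    reg["Global"] = ((), 8, None, False)
    reg["2DACorr"] = (PROPERTY_CHANNELS, 11, None, False)
    reg["3DACorr"] = (PROPERTY_CHANNELS, ACORR3D_BINS, ACORR3D_BIN_WIDTH, True)
    reg["RDF"] = (PROPERTY_CHANNELS, RDF_BINS, RDF_BIN_WIDTH, True)
    reg["SurfACorr"] = ((), 36, None, False)
    return reg


def registry_total(registry: DescriptorRegistry | None = None) -> int:
    """Total declared descriptor count (default registry: 1252)."""
    if registry is None:
        registry = default_registry()
    return registry.total()


def bin_range(family: str, k: int) -> tuple:
    """Distance range [lo, hi) in Å named by bin index ``k``.

    ``RDF`` index k covers [(k−1)·0.1, k·0.1); ``3DACorr`` index k covers
    [k, k+1) — so RDF_*_86 ↔ 8.5–8.6 Å and 3DACorr_*_9 ↔ 9–10 Å, matching
    the naming convention of the original descriptor program.
    """
    if family == "RDF":
        if not 1 <= k <= RDF_BINS:
            raise ValueError(f"RDF bin index {k} outside 1..{RDF_BINS}")
        return ((k - 1) * RDF_BIN_WIDTH, k * RDF_BIN_WIDTH)
    if family == "3DACorr":
        if not 1 <= k <= ACORR3D_BINS:
            raise ValueError(f"3DACorr bin index {k} outside 1..{ACORR3D_BINS}")
        return (float(k), float(k + 1))
    raise ValueError(f"no binned family named {family!r}")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _pair_arrays(mol: Molecule3D, channel):
    p = np.asarray(mol.properties[channel] if isinstance(channel, str)
                   else channel, dtype=float)
    xyz = mol.coordinates
    if len(p) != len(xyz):
        raise ValueError("property channel length does not match atom count")
    iu, ju = np.triu_indices(len(p), k=1)
    rij = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
    w = p[iu] * p[ju]
    return rij, w


def rdf_profile(mol: Molecule3D, channel, B: float = DEFAULT_RDF_B,
                eval_at: str = "midpoint") -> np.ndarray:
    """All 128 RDF values for one property channel."""
    rij, w = _pair_arrays(mol, channel)
    edges = np.arange(RDF_BINS) * RDF_BIN_WIDTH
    r_eval = edges + (RDF_BIN_WIDTH / 2 if eval_at == "midpoint" else 0.0)
    if eval_at not in ("midpoint", "left"):
        raise ValueError("eval_at must be 'midpoint' or 'left'")
    if len(rij) == 0:
        return np.zeros(RDF_BINS)
    diff = r_eval[:, None] - rij[None, :]
    return np.exp(-B * diff ** 2) @ w


def rdf(mol: Molecule3D, channel, k: int, B: float = DEFAULT_RDF_B,
        eval_at: str = "midpoint") -> float:
    """RDF descriptor at named bin ``k`` (1..128)."""
    if not 1 <= int(k) <= RDF_BINS:
        raise ValueError(f"RDF bin index {k} outside 1..{RDF_BINS}")
    return float(rdf_profile(mol, channel, B=B, eval_at=eval_at)[int(k) - 1])


def autocorr3d_profile(mol: Molecule3D, channel) -> np.ndarray:
    """All 12 spatial autocorrelation values for one property channel."""
    rij, w = _pair_arrays(mol, channel)
    out = np.zeros(ACORR3D_BINS)
    if len(rij) == 0:
        return out
    which = np.floor(rij).astype(int)  # pair at r ∈ [k, k+1) → bin k
    mask = (which >= 1) & (which <= ACORR3D_BINS)
    np.add.at(out, which[mask] - 1, w[mask])
    return out


def autocorr3d(mol: Molecule3D, channel, k: int) -> float:
    """3D autocorrelation descriptor at named bin ``k`` (1..12)."""
    if not 1 <= int(k) <= ACORR3D_BINS:
        raise ValueError(f"3DACorr bin index {k} outside 1..{ACORR3D_BINS}")
    return float(autocorr3d_profile(mol, channel)[int(k) - 1])


# ---------------------------------------------------------------------------
# the full vector
# ---------------------------------------------------------------------------

def ensure_channels(mol: Molecule3D) -> None:
    """Populate all eight property channels on ``mol`` if missing."""
    if "SigChg" not in mol.properties:
        compute_channels(mol)
    props = mol.properties
    if "SigEN" not in props:
        props["SigEN"] = residual_en(mol, props["SigChg"])
    if "PiEN" not in props:
        pi = np.asarray(props["PiChg"], dtype=float)
        props["PiEN"] = np.where(pi != 0.0, residual_en(mol, pi), 0.0)
    if "Polariz" not in props:
        props["Polariz"] = np.array(
            [_POLARIZABILITY.get(sym, 0.0) for sym, _, _ in mol.atoms])
    if "Ident" not in props:
        props["Ident"] = np.ones(mol.n_atoms)


def compute_all(mol: Molecule3D, B: float = DEFAULT_RDF_B,
                eval_at: str = "midpoint",
                registry: DescriptorRegistry | None = None) -> dict:
    """All computable descriptors for one molecule, name → value.

    Covers the RDF and 3DACorr families over the eight property channels
    (1120 values).  Registry families flagged non-computable are *not*
    present in the output; their names remain available from the registry.
    """
    if mol.n_atoms < 2:
        raise ValueError(f"{mol.id}: descriptor computation needs ≥2 atoms")
    if registry is None:
        registry = default_registry()
    ensure_channels(mol)
    out = {}
    for family in ("3DACorr", "RDF"):
        props, bins, _, computable = registry.get(family, ((), 0, None, False))
        if not computable:
            continue
        for prop in props:
            profile = (rdf_profile(mol, prop, B=B, eval_at=eval_at)
                       if family == "RDF" else autocorr3d_profile(mol, prop))
            for k in range(1, bins + 1):
                out[f"{family}_{prop}_{k}"] = float(profile[k - 1])
    return out


def descriptor_matrix(mols, B: float = DEFAULT_RDF_B,
                      eval_at: str = "midpoint") -> "pandas.DataFrame":
    """Descriptor matrix for several molecules (rows: molecule ids)."""
    import pandas as pd

    rows = {mol.id: compute_all(mol, B=B, eval_at=eval_at) for mol in mols}
    return pd.DataFrame.from_dict(rows, orient="index")
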