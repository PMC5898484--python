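"""Conformational-ensemble observables for disordered-chain models.

Computes the quantities typically read from molecular-dynamics or polymer
ensembles of intrinsically disordered proteins: end-to-end distance R_E,
radius of gyration R_G, per-residue RMSF and its crystallographic B-factor
conversion, dihedral-based helical fractions, and the ensemble-averaged FRET
efficiency between two labelled sites.

Coordinates are held in nm internally; PDB I/O converts from/to Angstrom and
B-factors are reported in A^2 per crystallographic convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConformerEnsemble",
    "FretParameters",
    "EnsembleReport",
    "end_to_end",
    "radius_of_gyration",
    "rmsf",
    "bfactor",
    "helical_fraction",
    "mean_fret",
    "ensemble_report",
]

NM_PER_ANGSTROM = 0.1

#: Default Forster radius in nm for the Alexa488/Alexa594 dye pair
#: (literature convention for this donor/acceptor combination).
DEFAULT_R0_NM = 5.4

#: Default alpha-helical Ramachandran basin (phi, psi in degrees).
ALPHA_PHI = (-100.0, -30.0)
ALPHA_PSI = (-67.0, -7.0)


@dataclass
class ConformerEnsemble:
    """Multi-model per-residue coordinates, optionally with backbone dihedrals.

    ``coords`` has shape (n_models, n_residues, 3) in nm; ``dihedrals``
    (n_models, n_residues, 2) in degrees (phi, psi; NaN where undefined).
    """

    coords: np.ndarray
    dihedrals: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_residues, 3)")
        if self.coords.shape[1] < 2:
            raise ValueError("ensemble needs at least 2 residues")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.dihedrals is not None:
            self.dihedrals = np.asarray(self.dihedrals, float)
            if self.dihedrals.shape[:2] != self.coords.shape[:2]:
                raise ValueError("dihedrals must match coords in models and residues")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_pdb(cls, path: str | Path) -> "ConformerEnsemble":
        """Read a multi-model PDB (MODEL/ENDMDL records), Calpha trace.

        Coordinates are converted from Angstrom to nm.  Calpha-only files
        are accepted; for full-backbone files only CA atoms are kept.
        """
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(str(path))
        stack = pdb.get_structure(f)  # AtomArrayStack, coords in Angstrom
        ca = stack[:, stack.atom_name == "CA"]
        return cls(coords=ca.coord * NM_PER_ANGSTROM)

    def to_pdb(self, path: str | Path) -> None:
        """Write a Calpha-only multi-model PDB (coordinates in Angstrom)."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n_res = self.n_residues
        arr = struc.AtomArray(n_res)
        arr.coord = self.coords[0] / NM_PER_ANGSTROM
        arr.atom_name = np.full(n_res, "CA")
        arr.res_name = np.full(n_res, "GLY")
        arr.res_id = np.arange(1, n_res + 1)
        arr.chain_id = np.full(n_res, "A")
        arr.element = np.full(n_res, "C")
        stack = struc.stack([arr] * self.n_models)
        stack.coord = self.coords / NM_PER_ANGSTROM
        f = pdb.PDBFile()
        pdb.set_structure(f, stack)
        f.write(str(path))

    @classmethod
    def from_xyz(cls, path: str | Path) -> "ConformerEnsemble":
        """Read a plain-text XYZ table: blank-line-separated models of
        three-column (x y z, in nm) rows."""
        text = Path(path).read_text()
        blocks = [b for b in text.strip().split("\n\n") if b.strip()]
        models = [np.loadtxt(b.splitlines(), comments="#", ndmin=2) for b in blocks]
        return cls(coords=np.stack(models))

    def to_xyz(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# x_nm y_nm z_nm; models separated by blank lines\n")
            for m in self.coords:
                np.savetxt(fh, m, fmt="%.6f")
                fh.write("\n")


@dataclass(frozen=True)
class FretParameters:
    """Forster radius (nm) and labelled-site residue indices."""

    r0: float = DEFAULT_R0_NM
    donor_site: int = 0
    acceptor_site: int = -1

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


def end_to_end(ensemble: ConformerEnsemble, i: int = 0, j: int = -1) -> np.ndarray:
    """Per-model Euclidean distance (nm) between residues i and j."""
    n = ensemble.n_residues
    i, j = i % n, j % n
    if i == j:
        raise ValueError("end-to-end distance requires two distinct residues")
    return np.linalg.norm(ensemble.coords[:, j] - ensemble.coords[:, i], axis=1)


def radius_of_gyration(ensemble: ConformerEnsemble) -> np.ndarray:
    """Per-model mass-uniform radius of gyration (nm) about the centroid."""
    centered = ensemble.coords - ensemble.coords.mean(axis=1, keepdims=True)
    return np.sqrt((centered**2).sum(axis=2).mean(axis=1))


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``ref`` (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    u, _, vt = np.linalg.svd(mc.T @ rc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + ref.mean(axis=0)


def rmsf(ensemble: ConformerEnsemble, superpose: bool = True, n_iter: int = 2) -> np.ndarray:
    """Per-residue root-mean-square fluctuation (nm) about the mean structure.

    With ``superpose`` each model is least-squares fitted onto the ensemble
    mean structure; the reference is refined over ``n_iter`` iterations
    (mean -> fit -> new mean), the standard fluctuation-analysis procedure.
    """
    if ensemble.n_models < 2:
        raise ValueError("RMSF needs at least 2 models")
    coords = ensemble.coords
    if superpose:
        for _ in range(n_iter):
            ref = coords.mean(axis=0)
            coords = np.stack([_kabsch(m, ref) for m in coords])
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def bfactor(rmsf_nm: np.ndarray) -> np.ndarray:
    """Isotropic B-factor (A^2) from RMSF (nm): B = (8 pi^2 / 3) RMSF_A^2."""
    rmsf_nm = np.asarray(rmsf_nm, float)
    if (rmsf_nm < 0).any():
        raise ValueError("RMSF must be nonnegative")
    rmsf_angstrom = rmsf_nm * 10.0
    return (8.0 * math.pi**2 / 3.0) * rmsf_angstrom**2


def helical_fraction(
    ensemble: ConformerEnsemble,
    window: int = 4,
    phi_range: tuple[float, float] = ALPHA_PHI,
    psi_range: tuple[float, float] = ALPHA_PSI,
) -> np.ndarray:
    """Per-residue fraction of models in which the residue is alpha-helical.

    A residue counts as helical in a model when its (phi, psi) lies in the
    alpha basin and belongs to a run of at least ``window`` consecutive
    such residues — a minimal dihedral-based criterion that needs no
    hydrogen positions.
    """
    if ensemble.dihedrals is None:
        raise ValueError("ensemble carries no backbone dihedrals")
    phi = ensemble.dihedrals[:, :, 0]
    psi = ensemble.dihedrals[:, :, 1]
    in_basin = (
        (phi >= phi_range[0]) & (phi <= phi_range[1])
        & (psi >= psi_range[0]) & (psi <= psi_range[1])
    )
    in_basin &= np.isfinite(phi) & np.isfinite(psi)
    n_models, n_res = in_basin.shape
    helical = np.zeros_like(in_basin)
    for m in range(n_models):
        run = 0
        for r in range(n_res):
            if in_basin[m, r]:
                run += 1
                if run >= window:
                    helical[m, r - run + 1: r + 1] = True
            else:
                run = 0
    return helical.mean(axis=0)


def mean_fret(ensemble: ConformerEnsemble, params: FretParameters) -> tuple[float, np.ndarray]:
    """Ensemble-averaged FRET efficiency and the per-model distribution.

    Per model E = 1 / (1 + (r / R0)^6) at the labelled-site distance,
    assuming isotropic dye orientations and orientational averaging fast
    compared to the transfer time; the ensemble mean assumes conformations
    static on the fluorescence timescale.
    """
    r = end_to_end(ensemble, params.donor_site, params.acceptor_site)
    with np.errstate(divide="ignore"):
        e = 1.0 / (1.0 + (r / params.r0) ** 6)
    e = np.where(r == 0, 1.0, e)
    return float(e.mean()), e


@dataclass
class EnsembleReport:
    """Summary observables of a conformer ensemble."""

    mean_re: float
    re_distribution: np.ndarray
    mean_rg: float
    rmsf_nm: np.ndarray
    bfactor_a2: np.ndarray
    helical_per_residue: np.ndarray | None
    helical_overall: float | None
    mean_efret: float | None

    def to_dataframe(self):
        import pandas as pd

        data = {"residue": np.arange(len(self.rmsf_nm)),
                "rmsf_nm": self.rmsf_nm, "bfactor_A2": self.bfactor_a2}
        if self.helical_per_residue is not None:
            data["helical_fraction"] = self.helical_per_residue
        return pd.DataFrame(data)


def ensemble_report(
    ensemble: ConformerEnsemble,
    fret_params: FretParameters | None = None,
    helix_window: int = 4,
    superpose: bool = True,
) -> EnsembleReport:
    """Compute the full observable set for an ensemble in one call."""
    re = end_to_end(ensemble)
    rg = radius_of_gyration(ensemble)
    fl = rmsf(ensemble, superpose=superpose)
    hel = hel_overall = None
    if ensemble.dihedrals is not None:
        hel = helical_fraction(ensemble, window=helix_window)
        hel_overall = float(hel.mean())
    me = None
    if fret_params is not None:
        me, _ = mean_fret(ensemble, fret_params)
    return EnsembleReport(
        mean_re=float(re.mean()), re_distribution=re, mean_rg=float(rg.mean()),
        rmsf_nm=fl, bfactor_a2=bfactor(fl),
        helical_per_residue=hel, helical_overall=hel_overall, mean_efret=me,
    )
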