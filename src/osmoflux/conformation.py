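"""Geometry of flexible-molecule conformer ensembles.

Flexible peptides have no single conformational minimum, so their size is
summarised statistically over an ensemble of conformers: the mass-weighted
radius of gyration

    Rg² = (1/M) Σᵢ mᵢ ‖Rᵢ − R_CM‖²,   R_CM = (1/M) Σᵢ mᵢ Rᵢ

computed per frame over heavy atoms, plus structural clustering of frames
by pairwise optimal-superposition RMSD to identify the dominant
conformations and their medoid representatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, ClusterMixin

from .elements import is_heavy, mass_of
from .models import ClusterResult, ConfigurationError, EnsembleError, RgResult

__all__ = [
    "AtomRecord",
    "ConformerEnsemble",
    "center_of_mass",
    "radius_of_gyration",
    "ensemble_rg",
    "superpose_rmsd",
    "ConformerClusterer",
    "cluster_frames",
]

_LINKAGE_METHODS = {"single", "complete", "average", "weighted", "centroid", "median", "ward"}


@dataclass
class AtomRecord:
    """One atom: element symbol, mass (Da) and Cartesian position (Å)."""

    element: str
    position: tuple[float, float, float]
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.mass is None:
            self.mass = mass_of(self.element)
        if self.mass <= 0:
            raise EnsembleError(f"atom mass must be > 0, got {self.mass}")
        if not np.all(np.isfinite(self.position)):
            raise EnsembleError(f"non-finite position: {self.position}")

    @property
    def is_heavy(self) -> bool:
        return is_heavy(self.element)


@dataclass
class ConformerEnsemble:
    """A multi-frame conformer set with a shared topology.

    coords has shape (n_frames, n_atoms, 3) in Å; elements and masses are
    per-atom and identical across frames.
    """

    coords: np.ndarray
    elements: np.ndarray
    masses: np.ndarray = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError(
                f"coords must have shape (n_frames, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        self.elements = np.asarray(
            [str(e).strip().upper() for e in np.asarray(self.elements).ravel()]
        )
        if self.elements.shape[0] != self.coords.shape[1]:
            raise EnsembleError(
                "elements length does not match the atom count: "
                f"{self.elements.shape[0]} vs {self.coords.shape[1]}"
            )
        if self.masses is None:
            self.masses = np.array([mass_of(e) for e in self.elements])
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        if self.masses.shape[0] != self.coords.shape[1]:
            raise EnsembleError("masses length does not match the atom count")
        if np.any(self.masses <= 0):
            raise EnsembleError("all atom masses must be > 0")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleError(
                "ensemble contains non-finite coordinates; frames with "
                "missing atoms are rejected, not skipped"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([is_heavy(e) for e in self.elements])

    @classmethod
    def from_frames(
        cls, frames: list[list[AtomRecord]], label: str = ""
    ) -> "ConformerEnsemble":
        """Build from lists of AtomRecord, enforcing identical topology."""
        if not frames:
            raise EnsembleError("ensemble needs at least one frame")
        ref = frames[0]
        elements = [a.element.strip().upper() for a in ref]
        masses = [a.mass for a in ref]
        coords = np.empty((len(frames), len(ref), 3))
        for i, frame in enumerate(frames):
            if len(frame) != len(ref):
                raise EnsembleError(
                    f"frame {i} has {len(frame)} atoms, expected {len(ref)}"
                )
            for j, atom in enumerate(frame):
                if atom.element.strip().upper() != elements[j]:
                    raise EnsembleError(
                        f"frame {i} atom {j}: element {atom.element!r} "
                        f"differs from frame 0 ({elements[j]!r})"
                    )
                if atom.mass != masses[j]:
                    raise EnsembleError(
                        f"frame {i} atom {j}: mass differs from frame 0"
                    )
                coords[i, j] = atom.position
        return cls(coords=coords, elements=np.array(elements),
                   masses=np.array(masses), label=label)


def _selection(
    coords: np.ndarray,
    masses: np.ndarray,
    elements: np.ndarray | None,
    heavy_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if heavy_only:
        if elements is None:
            raise EnsembleError("heavy_only selection requires element symbols")
        mask = np.array([is_heavy(e) for e in elements])
        coords, masses = coords[mask], masses[mask]
    if coords.shape[0] == 0:
        raise EnsembleError("selection is empty (no heavy atoms?)")
    return coords, masses


def _coerce_frame(
    atoms, heavy_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of AtomRecord or (coords, masses[, elements]) arrays."""
    if isinstance(atoms, (list, tuple)) and atoms and isinstance(atoms[0], AtomRecord):
        coords = np.array([a.position for a in atoms], dtype=float)
        masses = np.array([a.mass for a in atoms], dtype=float)
        elements = np.array([a.element for a in atoms])
        return _selection(coords, masses, elements, heavy_only)
    raise TypeError("expected a list of AtomRecord")


def center_of_mass(atoms: list[AtomRecord], heavy_only: bool = True) -> np.ndarray:
    """Mass-weighted mean position R_CM = (1/M) Σ mᵢRᵢ, in Å."""
    coords, masses = _coerce_frame(atoms, heavy_only)
    return masses @ coords / masses.sum()


def radius_of_gyration(atoms: list[AtomRecord], heavy_only: bool = True) -> float:
    """Mass-weighted radius of gyration of one conformer, in Å.

    Rg = sqrt( Σ mᵢ‖Rᵢ − R_CM‖² / M ) over the selected atoms; by default
    hydrogens are excluded and M is the mass of the same selection.
    """
    coords, masses = _coerce_frame(atoms, heavy_only)
    return _rg_arrays(coords, masses)


def _rg_arrays(coords: np.ndarray, masses: np.ndarray) -> float:
    com = masses @ coords / masses.sum()
    dev2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(masses @ dev2 / masses.sum()))


def ensemble_rg(ens: ConformerEnsemble, heavy_only: bool = True) -> RgResult:
    """Per-frame Rg over an ensemble with mean and sample SD (Å)."""
    if ens.n_frames < 1:
        raise EnsembleError("ensemble has no frames")
    if heavy_only:
        mask = ens.heavy_mask
        if not mask.any():
            raise EnsembleError("selection is empty (no heavy atoms?)")
    else:
        mask = np.ones(ens.n_atoms, dtype=bool)
    masses = ens.masses[mask]
    per_frame = [_rg_arrays(ens.coords[i][mask], masses) for i in range(ens.n_frames)]
    arr = np.asarray(per_frame)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RgResult(
        per_frame_rg=[float(r) for r in per_frame],
        mean=float(arr.mean()),
        sd=sd,
        heavy_only=heavy_only,
    )


def superpose_rmsd(a, b, heavy_only: bool = False) -> float:
    """Minimum RMSD (Å) between two conformers over rigid motions.

    Centres both frames and solves the optimal-rotation (Kabsch) problem;
    plain coordinate RMSD, no mass weighting.  ``a`` and ``b`` may be
    (n, 3) arrays or lists of AtomRecord.
    """
    xa, xb = (_as_coords(f, heavy_only) for f in (a, b))
    if xa.shape != xb.shape:
        raise EnsembleError(
            f"frames are not conformable: {xa.shape} vs {xb.shape}"
        )
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    rot, _ = Rotation.align_vectors(xa, xb)
    # recompute the residual explicitly: the solver's rssd loses ~sqrt(eps)
    # precision to cancellation for near-identical frames
    resid = xa - rot.apply(xb)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def _as_coords(frame, heavy_only: bool) -> np.ndarray:
    if isinstance(frame, (list, tuple)) and frame and isinstance(frame[0], AtomRecord):
        coords, _ = _coerce_frame(frame, heavy_only)
        return coords
    arr = np.asarray(frame, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise EnsembleError(f"expected (n, 3) coordinates, got {arr.shape}")
    return arr


class ConformerClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of conformers on pairwise superposition RMSD.

    Parameters
    ----------
    linkage : str, default "average"
        Any scipy hierarchical linkage method.
    cutoff : float, default 2.0
        Flat-cluster distance threshold, Å of RMSD.
    heavy_only : bool, default True
        Restrict the RMSD to heavy atoms.

    Attributes
    ----------
    labels_ : ndarray of shape (n_frames,)
        1-based flat cluster ids (scipy convention).
    distance_matrix_ : ndarray of shape (n_frames, n_frames)
        Pairwise minimum RMSD.
    representatives_ : dict
        cluster id → medoid frame index (minimum summed within-cluster RMSD).
    """

    def __init__(self, linkage: str = "average", cutoff: float = 2.0,
                 heavy_only: bool = True):
        self.linkage = linkage
        self.cutoff = cutoff
        self.heavy_only = heavy_only

    def fit(self, X, y=None):
        if self.linkage not in _LINKAGE_METHODS:
            raise ConfigurationError(
                f"unknown linkage {self.linkage!r}; "
                f"choose one of {sorted(_LINKAGE_METHODS)}"
            )
        if isinstance(X, ConformerEnsemble):
            mask = X.heavy_mask if self.heavy_only else np.ones(X.n_atoms, bool)
            frames = X.coords[:, mask, :]
        else:
            frames = np.asarray(X, dtype=float)
            if frames.ndim != 3:
                raise EnsembleError(
                    "expected a ConformerEnsemble or (n_frames, n_atoms, 3) array"
                )
        n = frames.shape[0]
        if n < 2:
            raise EnsembleError("clustering needs at least two frames")
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = superpose_rmsd(frames[i], frames[j])
        Z = scipy_linkage(squareform(dm, checks=False), method=self.linkage)
        labels = fcluster(Z, t=self.cutoff, criterion="distance")
        reps: dict[int, int] = {}
        for cid in np.unique(labels):
            members = np.flatnonzero(labels == cid)
            sums = dm[np.ix_(members, members)].sum(axis=1)
            reps[int(cid)] = int(members[int(np.argmin(sums))])
        self.distance_matrix_ = dm
        self.labels_ = labels
        self.representatives_ = reps
        return self

    def to_result(self) -> ClusterResult:
        return ClusterResult(
            assignments={i: int(c) for i, c in enumerate(self.labels_)},
            linkage=self.linkage,
            cutoff=self.cutoff,
            representatives=dict(self.representatives_),
        )


def cluster_frames(
    ens: ConformerEnsemble,
    linkage: str = "average",
    cutoff: float = 2.0,
    heavy_only: bool = True,
) -> ClusterResult:
    """Hierarchically cluster ensemble frames by superposition RMSD.

    Thin wrapper around :class:`ConformerClusterer`.
    """
    clusterer = ConformerClusterer(linkage=linkage, cutoff=cutoff,
                                   heavy_only=heavy_only)
    return clusterer.fit(ens).to_result()
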