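"""Spherical head model: parcellated source space, montage and lead field.

The cortex is represented by a tessellated sphere partitioned into
contiguous regions, each carrying a radially oriented equivalent current
dipole at its centroid.  Scalp potentials are computed with the analytic
solution for a dipole inside three concentric homogeneous spherical shells
(brain, skull, scalp), expanded in Legendre polynomials.  A loader accepts
externally computed lead fields (e.g. from a boundary-element model) so
realistic anatomy can be swapped in without touching the rest of the
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "SourceSpace",
    "ElectrodeMontage",
    "ShellModel",
    "LeadField",
    "build_spherical_source_space",
    "standard_montage_1010",
    "analytic_three_shell_leadfield",
    "project_to_sensors",
    "save_leadfield",
    "load_leadfield",
    "load_leadfield_tables",
]

#: 76 electrode labels of the extended 10-10 system used throughout
MONTAGE_76_LABELS = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 F9 F7 F5 F3 F1 Fz F2 F4 F6 F8 F10 "
    "FT9 FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 FT10 T9 T7 C5 C3 C1 Cz C2 C4 "
    "C6 T8 T10 TP9 TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 TP10 P9 P7 P5 P3 P1 "
    "Pz P2 P4 P6 P8 P10 PO9 PO7 PO3 POz PO4 PO8 PO10 O1 Oz O2 I1 Iz I2"
).split()


@dataclass
class SourceSpace:
    """Parcellated spherical cortex.

    ``centroids`` (m) hold one dipole location per region, ``adjacency`` is
    a symmetric boolean sparse matrix of region neighborhood (shared mesh
    edge), ``region_area`` (m^2) the tessellated area and ``orientation``
    the unit dipole orientation (radial).
    """

    centroids: np.ndarray
    adjacency: sparse.csr_matrix
    region_area: np.ndarray
    orientation: np.ndarray
    radius: float = 0.078

    @property
    def region_count(self) -> int:
        return self.centroids.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i].indices

    def mean_neighbor_spacing(self) -> float:
        """Mean centroid distance between adjacent regions (m)."""
        coo = sparse.triu(self.adjacency, 1).tocoo()
        d = np.linalg.norm(self.centroids[coo.row] - self.centroids[coo.col], axis=1)
        return float(d.mean())

    def save(self, prefix) -> None:
        """Write centroid table and adjacency edge list as delimited text."""
        np.savetxt(str(prefix) + "_centroids.txt", self.centroids)
        coo = sparse.triu(self.adjacency, 1).tocoo()
        np.savetxt(str(prefix) + "_edges.txt",
                   np.c_[coo.row, coo.col], fmt="%d")


@dataclass
class ElectrodeMontage:
    labels: list
    positions: np.ndarray  # (n, 3) m, on the outer shell
    reference: str = "CPz"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("labels and positions disagree in length")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for lab, (x, y, z) in zip(self.labels, self.positions):
                fh.write(f"{lab}\t{x:.8e}\t{y:.8e}\t{z:.8e}\n")

    @classmethod
    def load(cls, path, reference: str = "CPz") -> "ElectrodeMontage":
        labels, pos = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                pos.append([float(v) for v in parts[1:4]])
        return cls(labels, np.asarray(pos), reference)


@dataclass(frozen=True)
class ShellModel:
    """Concentric-shell radii (m) and conductivities (S/m), inside out."""

    radii: tuple = (0.087, 0.092, 0.100)
    conductivities: tuple = (0.33, 0.0042, 0.33)

    def __post_init__(self) -> None:
        if not all(r2 > r1 for r1, r2 in zip(self.radii, self.radii[1:])):
            raise ValueError("shell radii must be strictly increasing")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")


@dataclass
class LeadField:
    """Linear regions -> electrodes gain matrix (channels x regions)."""

    matrix: np.ndarray
    montage: ElectrodeMontage | None = None
    space: SourceSpace | None = None
    reference_scheme: str = "average"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead-field matrix contains non-finite entries")
        if self.space is not None and self.matrix.shape[1] != self.space.region_count:
            raise ValueError("lead-field column count != region count")
        if self.montage is not None and self.matrix.shape[0] != self.montage.n_channels:
            raise ValueError("lead-field row count != channel count")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]


def _icosphere(subdivisions: int, radius: float):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(mesh.vertices), np.asarray(mesh.faces)


def build_spherical_source_space(
    region_count: int,
    seed: int = 0,
    radius: float = 0.078,
    subdivisions: int | None = None,
) -> SourceSpace:
    """Parcellate a tessellated cortical sphere into contiguous regions.

    Region seeds are picked by farthest-point sampling (starting from a
    random vertex) and vertices are assigned to the nearest seed, which
    yields contiguous, roughly equal-area parcels.  Dipole orientations
    are radial.
    """
    if region_count < 10:
        raise ValueError("region_count must be >= 10")
    if subdivisions is None:
        subdivisions = 3
        while 4 ** subdivisions * 10 + 2 < 8 * region_count and subdivisions < 6:
            subdivisions += 1
    vertices, faces = _icosphere(subdivisions, radius)
    n_vert = vertices.shape[0]
    if region_count > n_vert // 4:
        raise ValueError(
            f"region_count {region_count} too large for a mesh of {n_vert} vertices"
        )

    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(n_vert))]
    min_d = np.linalg.norm(vertices - vertices[seeds[0]], axis=1)
    for _ in range(region_count - 1):
        nxt = int(np.argmax(min_d))
        seeds.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(vertices - vertices[nxt], axis=1))
    seed_pos = vertices[seeds]

    # nearest-seed assignment, chunked to bound memory
    assign = np.empty(n_vert, dtype=int)
    for lo in range(0, n_vert, 2048):
        hi = min(lo + 2048, n_vert)
        d = np.linalg.norm(vertices[lo:hi, None, :] - seed_pos[None], axis=2)
        assign[lo:hi] = np.argmin(d, axis=1)

    centroids = np.empty((region_count, 3))
    for r in range(region_count):
        mean = vertices[assign == r].mean(axis=0)
        centroids[r] = mean / np.linalg.norm(mean) * radius

    # vertex areas: one third of each incident triangle
    tri = vertices[faces]
    face_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    vert_area = np.zeros(n_vert)
    for k in range(3):
        np.add.at(vert_area, faces[:, k], face_area / 3.0)
    region_area = np.bincount(assign, weights=vert_area, minlength=region_count)

    # region adjacency from mesh edges crossing parcel borders
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    ra, rb = assign[edges[:, 0]], assign[edges[:, 1]]
    cross = ra != rb
    rows = np.concatenate([ra[cross], rb[cross]])
    cols = np.concatenate([rb[cross], ra[cross]])
    adj = sparse.csr_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)),
        shape=(region_count, region_count),
    )
    adj.sum_duplicates()
    adj.data[:] = True

    orientation = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    return SourceSpace(centroids, adj, region_area, orientation, radius)


def standard_montage_1010(
    scalp_radius: float = 0.100, reference: str = "CPz"
) -> ElectrodeMontage:
    """The packaged 76-channel 10-10 montage projected to the outer shell.

    Electrode directions come from the standard 10-05 template positions;
    each is radially projected onto the scalp sphere.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    positions = np.array([pos[lab] for lab in MONTAGE_76_LABELS])
    norms = np.linalg.norm(positions, axis=1, keepdims=True)
    return ElectrodeMontage(
        list(MONTAGE_76_LABELS), positions / norms * scalp_radius, reference
    )


def _legendre_terms(x: np.ndarray, n_max: int):
    """P_n(x) and P_n'(x) for n = 1..n_max by upward recurrence."""
    P = np.empty((n_max + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0], dP[0] = 1.0, 0.0
    P[1], dP[1] = x, 1.0
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P[1:], dP[1:]


def _shell_factors(shells: ShellModel, n_max: int) -> np.ndarray:
    """Per-order transfer factors F_n = V(scalp) / (unit source coefficient).

    For each Legendre order the radial part of the potential in shell *j*
    is ``A_j rho^n + B_j rho^-(n+1)`` (``rho = r / R_scalp``); continuity of
    potential and of radial current at the two interfaces plus the
    insulating outer boundary give a 5x5 linear system per order (B_1 is
    the known source coefficient, set to 1).
    """
    s1, s2, s3 = shells.conductivities
    R = shells.radii[2]
    r1, r2 = shells.radii[0] / R, shells.radii[1] / R
    F = np.empty(n_max)
    for n in range(1, n_max + 1):
        m = n + 1
        # unknowns: A1, A2, B2, A3, B3
        M = np.array([
            [r1**n, -r1**n, -r1**-m, 0.0, 0.0],
            [s1 * n * r1**(n - 1), -s2 * n * r1**(n - 1), s2 * m * r1**-(m + 1), 0.0, 0.0],
            [0.0, r2**n, r2**-m, -r2**n, -r2**-m],
            [0.0, s2 * n * r2**(n - 1), -s2 * m * r2**-(m + 1),
             -s3 * n * r2**(n - 1), s3 * m * r2**-(m + 1)],
            [0.0, 0.0, 0.0, n, -m],
        ])
        rhs = np.array([
            -r1**-m,
            s1 * m * r1**-(m + 1),
            0.0,
            0.0,
            0.0,
        ])
        A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
        F[n - 1] = A3 + B3  # potential at rho = 1
    return F


def analytic_three_shell_leadfield(
    space: SourceSpace,
    montage: ElectrodeMontage,
    shells: ShellModel = ShellModel(),
    n_terms: int = 60,
    reference: str = "average",
    tail_tol: float = 1e-6,
) -> LeadField:
    """Scalp potentials of unit dipoles in three concentric spherical shells.

    The potential of each regional dipole at each electrode is the
    truncated Legendre series of the concentric-shells boundary-value
    problem; with equal conductivities it reduces to the classical
    homogeneous-sphere dipole potential.  The matrix is common-average
    referenced by default.  Units: volts per unit dipole moment (A m).
    """
    R = shells.radii[2]
    src_r = np.linalg.norm(space.centroids, axis=1)
    if np.any(src_r >= shells.radii[0]):
        raise ValueError("all sources must lie strictly inside the innermost shell")
    elec = montage.positions
    if np.any(np.abs(np.linalg.norm(elec, axis=1) - R) > 1e-6):
        raise ValueError("electrodes must lie on the outer shell surface")

    e_hat = elec / R
    F = _shell_factors(shells, n_terms)
    sigma1 = shells.conductivities[0]

    n_arr = np.arange(1, n_terms + 1, dtype=float)
    mat = np.empty((montage.n_channels, space.region_count))
    for j in range(space.region_count):
        b_vec = space.centroids[j]
        b = src_r[j]
        b_hat = b_vec / b
        m = space.orientation[j]
        m_r = float(m @ b_hat)
        x = e_hat @ b_hat  # cos(angle source-electrode), per electrode
        P, dP = _legendre_terms(x, n_terms)  # (n_terms, n_chan)
        # tangential factor: m . (e_hat - x b_hat) -> multiplies P_n'
        tang = e_hat @ m - x * m_r
        coef = F * (b / R) ** (n_arr - 1) / (4.0 * np.pi * sigma1 * R**2)
        terms = coef[:, None] * (n_arr[:, None] * m_r * P + tang[None, :] * dP)
        total = terms.sum(axis=0)
        # geometric tail bound: the last 10 orders decay like rho = b/R per
        # order, so the neglected tail is below their sum times rho^10/(1-rho^10)
        rho = b / R
        increment = np.abs(terms[-10:].sum(axis=0)).max()
        tail = increment * rho**10 / (1.0 - rho**10)
        if tail > tail_tol * max(np.abs(total).max(), 1e-30):
            warnings.warn(
                f"Legendre series tail {tail:.2e} above tolerance for source {j}; "
                "increase n_terms", RuntimeWarning,
            )
        mat[:, j] = total

    scheme = reference
    if reference == "average":
        mat = mat - mat.mean(axis=0, keepdims=True)
    return LeadField(mat, montage, space, scheme)


def project_to_sensors(source: np.ndarray, lf: LeadField) -> np.ndarray:
    """Linear projection of region waveforms to electrodes: ``L @ source``."""
    source = np.asarray(source)
    if source.shape[0] != lf.n_regions:
        raise ValueError(
            f"source has {source.shape[0]} rows, lead field expects {lf.n_regions}"
        )
    return lf.matrix @ source


def save_leadfield(lf: LeadField, path) -> None:
    """Store matrix + montage + centroids in one HDF5 file with metadata."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=lf.matrix)
        fh.attrs["reference_scheme"] = lf.reference_scheme
        fh.attrs["units"] = "V / (A m)"
        if lf.montage is not None:
            fh.create_dataset("electrode_positions", data=lf.montage.positions)
            fh.create_dataset(
                "electrode_labels",
                data=np.array(lf.montage.labels, dtype="S"),
            )
            fh.attrs["reference_electrode"] = lf.montage.reference
        if lf.space is not None:
            fh.create_dataset("centroids", data=lf.space.centroids)


def load_leadfield(path) -> LeadField:
    """Round-trip loader for :func:`save_leadfield` files."""
    import h5py

    with h5py.File(path, "r") as fh:
        matrix = fh["matrix"][()]
        scheme = fh.attrs.get("reference_scheme", "unknown")
        montage = None
        if "electrode_positions" in fh:
            labels = [s.decode() for s in fh["electrode_labels"][()]]
            montage = ElectrodeMontage(
                labels, fh["electrode_positions"][()],
                fh.attrs.get("reference_electrode", ""),
            )
    return LeadField(matrix, montage, None, scheme)


def load_leadfield_tables(
    matrix_file, montage_file, centroid_file, re_reference: bool = True
) -> LeadField:
    """Load an externally computed lead field from delimited text tables.

    ``matrix_file`` holds the channels x regions gain matrix,
    ``montage_file`` rows of ``label x y z`` and ``centroid_file`` one
    ``x y z`` row per region.  Dimensions are validated and the matrix is
    re-referenced to the common average when requested.
    """
    matrix = np.loadtxt(matrix_file, ndmin=2)
    montage = ElectrodeMontage.load(montage_file)
    centroids = np.loadtxt(centroid_file, ndmin=2)
    if matrix.shape[0] != montage.n_channels:
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but montage {montage.n_channels} channels"
        )
    if matrix.shape[1] != centroids.shape[0]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but {centroids.shape[0]} centroids"
        )
    if not np.all(np.isfinite(matrix)):
        raise ValueError("lead-field matrix contains non-finite entries")
    scheme = "as-loaded"
    if re_reference:
        matrix = matrix - matrix.mean(axis=0, keepdims=True)
        scheme = "average"
    n = centroids.shape[0]
    space = SourceSpace(
        centroids,
        sparse.csr_matrix((n, n), dtype=bool),
        np.full(n, np.nan),
        centroids / np.maximum(np.linalg.norm(centroids, axis=1, keepdims=True), 1e-12),
    )
    return LeadField(matrix, montage, space, scheme)
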