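"""EEG forward model: 3-shell spherical head, lead fields, scalp mixing.

The quasi-static potential of a current dipole inside a 3-shell concentric
sphere (brain / skull / scalp) is computed from the spherical-harmonic
series: in each shell the potential is ``A_k r^n + B_k r^-(n+1)`` per degree
``n``; continuity of potential and radial current at the two inner
interfaces plus the insulating outer boundary give a 5x5 linear system per
degree, with the source term from the free-medium dipole expansion.  The
series is truncated when terms fall below 1e-12 of the running sum.

Two separate lead fields are built: ``LF1`` for the five neural dipoles
(brainstem, bilateral thalamus, bilateral primary auditory cortex) and
``LF2`` for the artifactual cochlear dipole, so that

    EEG_mix  = LF1 . S_n + LF2 . S_Art + b
    EEG_ASSR = LF1 . S_n

with dipole orientations folded into the fixed-orientation columns and ``b``
white Gaussian sensor noise.  ``EEG_ASSR`` is the uncontaminated control
dataset against which denoising is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cochlea import NoiseSpec
from .neuraldyn import SourceDynamics

__all__ = [
    "ShellModel",
    "Dipole",
    "Montage",
    "LeadField",
    "EEGDataset",
    "sphere_potential",
    "sphere_lead_field",
    "save_lead_field",
    "load_lead_field",
    "default_dipoles",
    "synthesize_eeg",
]

#: 32-channel 10-10 subset (actiCAP-style layout) used throughout.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
]

#: Fronto-central region of interest for ASSR scoring.
ROI_FRONTOCENTRAL = [
    "Fz", "F3", "F7", "FC5", "FC1", "C3", "Cz", "C4", "FC6", "FC2", "F4", "F8",
]


@dataclass(frozen=True)
class ShellModel:
    """Concentric brain/skull/scalp conductor geometry.

    Radii in meters (strictly increasing), conductivities in S/m.  The skull
    default honors the classical 1/80 scalp-to-skull conductivity ratio
    (0.33/80 = 0.004125 S/m); pass ``conductivities=(0.33, 0.042, 0.33)`` to
    use the alternative rounded value instead.
    """

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.33, 0.33 / 80.0, 0.33)

    def __post_init__(self) -> None:
        r1, r2, r3 = self.radii
        if not 0 < r1 < r2 < r3:
            raise ValueError("radii must satisfy 0 < brain < skull < scalp")
        if min(self.conductivities) <= 0:
            raise ValueError("conductivities must be strictly positive")

    @property
    def scalp_radius(self) -> float:
        return self.radii[2]

    @property
    def brain_radius(self) -> float:
        return self.radii[0]


@dataclass(frozen=True)
class Dipole:
    """Fixed-orientation current dipole in head-centered RAS coordinates."""

    position: np.ndarray  # (3,), meters
    orientation: np.ndarray  # (3,), unit vector
    role: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        ori = np.asarray(self.orientation, dtype=float)
        if pos.shape != (3,) or ori.shape != (3,):
            raise ValueError("position and orientation must be 3-vectors")
        norm = np.linalg.norm(ori)
        if norm == 0:
            raise ValueError("orientation must be nonzero")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori / norm)


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with unit direction vectors.

    Electrode positions are the unit vectors scaled to the scalp radius of
    whichever :class:`ShellModel` they are combined with.
    """

    labels: tuple[str, ...]
    directions: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if dirs.shape != (len(self.labels), 3):
            raise ValueError("directions shape must match labels")
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero electrode direction")
        object.__setattr__(self, "directions", dirs / norms)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def positions(self, radius: float) -> np.ndarray:
        return self.directions * radius

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def standard_32(cls) -> "Montage":
        """32-channel 10-10 montage from the bundled template positions."""
        import mne

        mont = mne.channels.make_standard_montage("colin27_1005")
        pos = mont.get_positions()["ch_pos"]
        dirs = np.array([pos[c] for c in CHANNELS_32])
        return cls(labels=tuple(CHANNELS_32), directions=dirs)


@dataclass(frozen=True)
class LeadField:
    """(n_electrodes x n_dipoles) map from dipole moments to potentials."""

    matrix: np.ndarray
    electrode_labels: tuple[str, ...]
    dipole_roles: tuple[str, ...]
    provenance: str = "analytic-sphere"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.electrode_labels), len(self.dipole_roles)):
            raise ValueError("lead-field shape inconsistent with labels/roles")
        if not np.all(np.isfinite(m)):
            raise ValueError("lead field must be finite")
        object.__setattr__(self, "matrix", m)


@dataclass
class EEGDataset:
    """Multichannel scalp potentials (microvolts) with scenario metadata."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    kind: str  # mix | assr | art | denoised | source
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("data must be finite")
        self.data = d

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def _legendre_terms(u: np.ndarray, nmax: int):
    """Yield (n, P_n(u), P_n'(u)) for n = 1..nmax via stable recurrences."""
    p_nm1 = np.ones_like(u)  # P_0
    p_n = u.copy()  # P_1
    dp_nm1 = np.zeros_like(u)  # P_0'
    dp_n = np.ones_like(u)  # P_1'
    for n in range(1, nmax + 1):
        yield n, p_n, dp_n
        p_np1 = ((2 * n + 1) * u * p_n - n * p_nm1) / (n + 1)
        dp_np1 = dp_nm1 + (2 * n + 1) * p_n
        p_nm1, p_n = p_n, p_np1
        dp_nm1, dp_n = dp_n, dp_np1


def _shell_transfer(shells: ShellModel, nmax: int) -> np.ndarray:
    """Scalp-surface potential per degree for unit source coefficient.

    For each degree ``n`` solve the 5-unknown radial system (A1; A2, B2;
    A3, B3) with the inner-shell source coefficient B1 = 1 and return
    ``T_n = A3 R^n + B3 R^-(n+1)`` evaluated at the scalp surface.  Radii are
    normalized by the scalp radius for conditioning.
    """
    r1, r2, r3 = (np.asarray(shells.radii) / shells.scalp_radius).tolist()
    s1, s2, s3 = shells.conductivities
    out = np.empty(nmax + 1)
    out[0] = 0.0
    for n in range(1, nmax + 1):
        # unknowns x = [A1, A2, B2, A3, B3]
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at r1: A1 r1^n + r1^-(n+1) = A2 r1^n + B2 r1^-(n+1)
        M[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0]
        rhs[0] = -(r1 ** -(n + 1))
        # current continuity at r1
        M[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0.0,
            0.0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        M[2] = [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # current continuity at r2
        M[3] = [
            0.0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulating outer boundary at r3: n A3 r3^(n-1) - (n+1) B3 r3^-(n+2) = 0
        M[4] = [0.0, 0.0, 0.0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        x = np.linalg.solve(M, rhs)
        out[n] = x[3] * r3**n + x[4] * r3 ** -(n + 1)
    return out


def sphere_potential(
    dipole: Dipole,
    electrode_positions: np.ndarray,
    shells: ShellModel,
    nmax: int = 200,
    rtol: float = 1e-12,
) -> np.ndarray:
    """Scalp potential per unit dipole moment at each electrode (V per A·m).

    Series truncation: terms are accumulated until the largest new term is
    below ``rtol`` of the running maximum, or ``nmax`` is reached (an error
    is raised if the series has not converged by then).
    """
    b_vec = np.asarray(dipole.position, dtype=float)
    b = np.linalg.norm(b_vec)
    if b >= shells.brain_radius:
        raise ValueError("dipole must lie strictly inside the brain shell")
    R = shells.scalp_radius
    elec = np.asarray(electrode_positions, dtype=float)
    r_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    q = dipole.orientation
    sigma1 = shells.conductivities[0]

    if b == 0.0:
        b_hat = np.array([0.0, 0.0, 1.0])
    else:
        b_hat = b_vec / b
    u = r_hat @ b_hat  # cos(gamma) per electrode
    q_r = float(q @ b_hat)
    # in-plane tangential unit vector at each electrode
    e_vec = r_hat - u[:, None] * b_hat
    sin_g = np.linalg.norm(e_vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hat = np.where(sin_g[:, None] > 0, e_vec / np.maximum(sin_g, 1e-300)[:, None], 0.0)
    q_e = e_hat @ q

    T = _shell_transfer(shells, nmax)
    V = np.zeros(elec.shape[0])
    vmax = 0.0
    converged = False
    t_ratio = b / R
    for n, p_n, dp_n in _legendre_terms(u, nmax):
        # b^(n-1) with normalized geometry: (b/R)^(n-1) / R^(n-1)
        radial = t_ratio ** (n - 1)
        ang = n * q_r * p_n + q_e * sin_g * dp_n
        term = T[n] * radial * ang
        V += term
        tmax = np.abs(term).max()
        vmax = max(vmax, np.abs(V).max())
        if n > 1 and vmax > 0 and tmax < rtol * vmax:
            converged = True
            break
        if b == 0.0:  # only n=1 contributes for a central dipole
            converged = True
            break
    if not converged:
        raise RuntimeError("spherical-harmonic series did not converge; raise nmax")
    return V / (4.0 * np.pi * sigma1 * R**2)


def sphere_lead_field(
    dipoles: Sequence[Dipole], montage: Montage, shells: ShellModel = ShellModel()
) -> LeadField:
    """Fixed-orientation lead field for ``dipoles`` at the montage electrodes."""
    elec = montage.positions(shells.scalp_radius)
    cols = [sphere_potential(d, elec, shells) for d in dipoles]
    return LeadField(
        matrix=np.column_stack(cols),
        electrode_labels=montage.labels,
        dipole_roles=tuple(d.role for d in dipoles),
        provenance="analytic-sphere",
    )


def save_lead_field(lf: LeadField, path: str | Path) -> None:
    """Write a lead field as a plain-text matrix with a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, lf.matrix)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "electrode_labels": list(lf.electrode_labels),
                "dipole_roles": list(lf.dipole_roles),
                "provenance": lf.provenance,
            },
            indent=1,
        )
    )


def load_lead_field(
    path: str | Path,
    expected_electrodes: Optional[Sequence[str]] = None,
    expected_roles: Optional[Sequence[str]] = None,
) -> LeadField:
    """Import an externally computed (e.g. BEM-derived) lead-field matrix."""
    path = Path(path)
    matrix = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    labels = tuple(meta["electrode_labels"])
    roles = tuple(meta["dipole_roles"])
    if matrix.size != len(labels) * len(roles):
        raise ValueError("lead-field shape inconsistent with sidecar labels/roles")
    matrix = matrix.reshape(len(labels), len(roles))
    if expected_electrodes is not None and tuple(expected_electrodes) != labels:
        raise ValueError("electrode labels of imported lead field do not match montage")
    if expected_roles is not None and tuple(expected_roles) != roles:
        raise ValueError("dipole roles of imported lead field do not match")
    return LeadField(matrix=matrix, electrode_labels=labels, dipole_roles=roles,
                     provenance="imported")


def default_dipoles(implant_side: str = "right") -> dict[str, list[Dipole]]:
    """Bundled dipole set: five neural dipoles plus the cochlear artifact.

    Positions are head-centered RAS (meters) placed in the anatomical
    neighborhoods of the generators (midline brainstem, bilateral thalamus,
    bilateral primary auditory cortex, cochlea in the temporal bone on the
    implant side).  Orientations are tuned so the neural topography
    focalizes fronto-centrally (Cz-max, as in scalp ASSR recordings) and the
    artifact spreads ipsilaterally from the implantation site.

    Returns a dict with keys ``"neural"`` (5 dipoles, order BS, Th_l, Th_r,
    A1_l, A1_r) and ``"artifact"`` (1 cochlear dipole).
    """
    if implant_side not in ("left", "right"):
        raise ValueError("implant_side must be 'left' or 'right'")
    sx = 1.0 if implant_side == "right" else -1.0
    neural = [
        Dipole(np.array([0.0, -0.030, -0.045]), np.array([0.0, 0.3, 1.0]), "brainstem"),
        Dipole(np.array([-0.012, -0.019, 0.004]), np.array([0.0, 0.3, 1.0]), "thalamus_l"),
        Dipole(np.array([0.012, -0.019, 0.004]), np.array([0.0, 0.3, 1.0]), "thalamus_r"),
        Dipole(np.array([-0.052, -0.020, 0.008]), np.array([0.15, 0.25, 1.0]), "a1_l"),
        Dipole(np.array([0.052, -0.020, 0.008]), np.array([-0.15, 0.25, 1.0]), "a1_r"),
    ]
    artifact = [
        Dipole(
            np.array([sx * 0.068, -0.012, -0.030]),
            np.array([sx * 1.0, -0.2, -0.3]),
            "cochlea",
        )
    ]
    return {"neural": neural, "artifact": artifact}


def synthesize_eeg(
    src: SourceDynamics,
    lf1: LeadField,
    lf2: LeadField,
    sensor_noise: NoiseSpec = NoiseSpec(std=1.0),
    seed: Optional[int] = None,
    neural_gain: float = 1.0,
    artifact_gain: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[EEGDataset, EEGDataset, EEGDataset]:
    """Project source dynamics to the scalp and add sensor noise.

    ``EEG_ASSR = LF1 . (g_n S_n)``, ``EEG_Art = LF2 . (g_a S_Art)``,
    ``EEG_mix = EEG_ASSR + EEG_Art + b`` with ``b`` i.i.d. Gaussian sensor
    noise per channel and sample (microvolts).  The gains are the
    calibration scalars mapping the arbitrary-unit sources to microvolts at
    the scalp.  Returns ``(mix, assr, art)`` sharing shape and labels.
    """
    if lf1.matrix.shape[1] != src.neural.shape[0]:
        raise ValueError("LF1 dipole count does not match neural source count")
    if lf2.matrix.shape[1] != 1:
        raise ValueError("LF2 must have exactly one (cochlear) dipole column")
    if lf1.electrode_labels != lf2.electrode_labels:
        raise ValueError("LF1/LF2 electrode sets differ")
    if rng is None:
        rng = np.random.default_rng(seed)
    assr = lf1.matrix @ (neural_gain * src.neural)
    art = lf2.matrix @ (artifact_gain * src.artifact[None, :])
    b = sensor_noise.mean + sensor_noise.std * rng.standard_normal(assr.shape)
    mix = assr + art + b
    labels = lf1.electrode_labels
    meta = {"neural_gain": neural_gain, "artifact_gain": artifact_gain,
            "sensor_noise_std": sensor_noise.std}
    mk = lambda d, kind: EEGDataset(
        data=d, sampling_rate_hz=src.sampling_rate_hz, channel_labels=labels,
        kind=kind, seed=seed, metadata=dict(meta),
    )
    return mk(mix, "mix"), mk(assr, "assr"), mk(art, "art")
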