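"""Wave geometry: distance equations, space-modified time, model catalogue.

A travelling wave aligns population cycles along an axis of *space-modified
time* ``rho = T + D / zeta`` where ``D`` is a signed distance (metres) from
either a planar front direction or a radial epicentre and ``zeta`` is the
constant wave speed (metres/day).  Twelve model structures are catalogued:

========  =====================================================  ===
label     hypothesis                                              K
========  =====================================================  ===
N1        null (intercept only)                                   0
N2        phase-locked / true synchrony (smooth of time)          0
N3        static spatial pattern (tensor smooth of X, Y)          0
P         single planar wave                                      2
RE / RC   single expanding / contracting radial wave              3
PF        two planar waves separated by a river                   4
PD        dual overlapping planar waves                           4
RFE/RFC   two expanding/contracting radial waves split by river   6
RDE/RDC   dual overlapping expanding/contracting radial waves     6
========  =====================================================  ===

K counts the wave parameters estimated outside the inner smoother and feeds
the adjusted-AIC penalty.  All coordinates are mean-centred metres; all
angles radians; this layer does no file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .smoother import SmoothSpec

__all__ = [
    "MODEL_LABELS",
    "MODEL_CATALOGUE",
    "ModelStructure",
    "WaveParameterSet",
    "planar_distance",
    "radial_distance",
    "space_modified_time",
    "build_design",
    "normalize_angle",
]

#: default northing (mean-centred metres) of the east-west river used by the
#: river-split models; observations with Y >= river_y belong to the north smooth
DEFAULT_RIVER_Y = 5068.0

WaveForm = Literal["planar", "radial-expanding", "radial-contracting"]


def planar_distance(X, Y, theta):
    """Signed distance of points from a planar wave front through the origin.

    ``D = sin(theta) * X + cos(theta) * Y`` — the projection of the
    (mean-centred) coordinates onto the direction of travel ``theta``
    (radians, clockwise from north).
    """
    return np.sin(theta) * np.asarray(X, float) + np.cos(theta) * np.asarray(Y, float)


def radial_distance(X, Y, gamma, psi, expanding=True):
    """Distance of points from a radial-wave epicentre ``(gamma, psi)``.

    Euclidean distance, negated for an expanding wave (points far from the
    epicentre lag the cycle) and positive for a contracting wave.
    """
    d = np.hypot(np.asarray(X, float) - gamma, np.asarray(Y, float) - psi)
    return -d if expanding else d


def space_modified_time(T, D, zeta):
    """``rho = T + D / zeta``: time shifted by signed distance over speed.

    As ``zeta`` grows without bound ``rho -> T`` everywhere: the true-synchrony
    limit where every location shares one cycle phase.
    """
    zeta = float(zeta)
    if zeta <= 0:
        raise ValueError(f"wave speed zeta must be > 0, got {zeta}")
    return np.asarray(T, float) + np.asarray(D, float) / zeta


def normalize_angle(theta: float) -> float:
    """Map an angle to the canonical reporting range [0, 2*pi)."""
    return float(np.mod(theta, 2.0 * np.pi))


@dataclass(frozen=True)
class ModelStructure:
    """Static description of one catalogue entry."""

    label: str
    kind: Literal["null", "single", "split", "dual"]
    forms: tuple[WaveForm, ...]  # one entry per wave; empty for nulls
    K: int  # number of wave parameters outside the smoother
    null_covariate: Literal[None, "time", "space"] = None

    @property
    def n_waves(self) -> int:
        return len(self.forms)


def _params_per_form(form: WaveForm) -> tuple[str, ...]:
    if form == "planar":
        return ("theta", "zeta")
    return ("gamma", "psi", "zeta")


MODEL_CATALOGUE: dict[str, ModelStructure] = {
    "N1": ModelStructure("N1", "null", (), 0),
    "N2": ModelStructure("N2", "null", (), 0, null_covariate="time"),
    "N3": ModelStructure("N3", "null", (), 0, null_covariate="space"),
    "P": ModelStructure("P", "single", ("planar",), 2),
    "RE": ModelStructure("RE", "single", ("radial-expanding",), 3),
    "RC": ModelStructure("RC", "single", ("radial-contracting",), 3),
    "PF": ModelStructure("PF", "split", ("planar", "planar"), 4),
    "RFE": ModelStructure("RFE", "split", ("radial-expanding",) * 2, 6),
    "RFC": ModelStructure("RFC", "split", ("radial-contracting",) * 2, 6),
    "PD": ModelStructure("PD", "dual", ("planar", "planar"), 4),
    "RDE": ModelStructure("RDE", "dual", ("radial-expanding",) * 2, 6),
    "RDC": ModelStructure("RDC", "dual", ("radial-contracting",) * 2, 6),
}

MODEL_LABELS: tuple[str, ...] = tuple(MODEL_CATALOGUE)


@dataclass
class WaveParameterSet:
    """Wave parameters for one catalogue entry.

    ``waves`` holds one dict per wave: ``{"theta": .., "zeta": ..}`` for a
    planar wave, ``{"gamma": .., "psi": .., "zeta": ..}`` for a radial one
    (coordinates mean-centred metres, speeds metres/day).  For the
    river-split models wave 0 is the northern wave and wave 1 the southern.
    """

    label: str
    waves: list[dict] = field(default_factory=list)

    def __post_init__(self):
        structure = MODEL_CATALOGUE.get(self.label)
        if structure is None:
            raise ValueError(f"unknown model label {self.label!r}")
        if len(self.waves) != structure.n_waves:
            raise ValueError(
                f"model {self.label} needs {structure.n_waves} wave(s), "
                f"got {len(self.waves)}"
            )
        for form, w in zip(structure.forms, self.waves):
            missing = set(_params_per_form(form)) - set(w)
            if missing:
                raise ValueError(f"wave parameters missing {sorted(missing)}")
            if w["zeta"] <= 0:
                raise ValueError("zeta must be > 0")
            if "theta" in w:
                w["theta"] = normalize_angle(w["theta"])

    @property
    def structure(self) -> ModelStructure:
        return MODEL_CATALOGUE[self.label]

    @property
    def K(self) -> int:
        return self.structure.K

    # flat vector view used by the optimizer: zeta on the log scale so that
    # multiplicative proposals stay positive
    def to_vector(self) -> np.ndarray:
        out = []
        for form, w in zip(self.structure.forms, self.waves):
            for name in _params_per_form(form):
                out.append(np.log(w[name]) if name == "zeta" else w[name])
        return np.asarray(out, float)

    @classmethod
    def from_vector(cls, label: str, vec) -> "WaveParameterSet":
        structure = MODEL_CATALOGUE[label]
        vec = np.asarray(vec, float)
        waves, k = [], 0
        for form in structure.forms:
            w = {}
            for name in _params_per_form(form):
                w[name] = float(np.exp(vec[k])) if name == "zeta" else float(vec[k])
                k += 1
            waves.append(w)
        if k != vec.size:
            raise ValueError(f"expected {k} parameters for {label}, got {vec.size}")
        return cls(label, waves)

    def parameter_names(self) -> list[str]:
        names = []
        for i, form in enumerate(self.structure.forms, start=1):
            for name in _params_per_form(form):
                names.append(name if len(self.waves) == 1 else f"{name}{i}")
        return names


def _wave_rho(form: WaveForm, w: dict, T, X, Y):
    if form == "planar":
        D = planar_distance(X, Y, w["theta"])
    elif form == "radial-expanding":
        D = radial_distance(X, Y, w["gamma"], w["psi"], expanding=True)
    elif form == "radial-contracting":
        D = radial_distance(X, Y, w["gamma"], w["psi"], expanding=False)
    else:
        raise ValueError(f"unknown wave form {form!r}")
    return space_modified_time(T, D, w["zeta"])


def build_design(
    label: str,
    params: WaveParameterSet | None,
    T,
    X,
    Y,
    river_y: float = DEFAULT_RIVER_Y,
    max_basis: int = 12,
    tensor_basis: int = 10,
) -> tuple[np.ndarray, list[SmoothSpec]]:
    """Covariate matrix and smooth layout for one model structure.

    Returns ``(Z, specs)`` where ``Z`` is an ``(n, m)`` covariate matrix and
    ``specs`` lists the smooth terms the inner GAM should fit on it.  Null
    models use raw time or space; wave models use space-modified time, one
    column per wave.  For the river-split models each observation enters
    exactly one smooth (north if ``Y >= river_y``, south otherwise); for the
    dual models every observation enters both smooths.
    """
    structure = MODEL_CATALOGUE.get(label)
    if structure is None:
        raise ValueError(f"unknown model label {label!r}")
    T = np.asarray(T, float)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = T.shape[0]

    if structure.kind == "null":
        if params is not None and params.waves:
            raise ValueError(f"model {label} takes no wave parameters")
        if structure.null_covariate is None:
            return np.empty((n, 0)), []
        if structure.null_covariate == "time":
            return T[:, None], [SmoothSpec(cols=(0,), max_basis=max_basis)]
        Z = np.column_stack([X, Y])
        return Z, [SmoothSpec(cols=(0, 1), max_basis=tensor_basis)]

    if params is None or params.label != label:
        raise ValueError(f"parameters for model {label} required")

    rhos = [
        _wave_rho(form, w, T, X, Y)
        for form, w in zip(structure.forms, params.waves)
    ]

    if structure.kind == "single":
        return rhos[0][:, None], [SmoothSpec(cols=(0,), max_basis=max_basis)]

    Z = np.column_stack(rhos)
    if structure.kind == "dual":
        return Z, [
            SmoothSpec(cols=(0,), max_basis=max_basis),
            SmoothSpec(cols=(1,), max_basis=max_basis),
        ]

    # river split: wave 0 applies north of the river, wave 1 south
    north = Y >= river_y
    return Z, [
        SmoothSpec(cols=(0,), rows=north, max_basis=max_basis),
        SmoothSpec(cols=(1,), rows=~north, max_basis=max_basis),
    ]
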