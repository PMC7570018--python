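"""Mesoscale network model: polar filaments, kinesin multimer linkers, end joints.

The model mirrors the reconstructed artificial-muscle scene: rigid
microtubule cylinders with distinct minus/plus ends, streptavidin-hubbed
kinesin multimers whose heads ride on filaments, and ball joints where
filament ends meet inside an aster fragment.  Two unit systems are used:
``"um"`` for models fitted from microscope volumes and ``"sim"`` for the
dimensionless dynamics scene (filament length 4.0, diameter 0.2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

MAX_BODIES = 1000  # empirical rigid-body budget of the scene engine

MODEL_SCHEMA = "mtmesh-network/1"

# Default simulation-scene dimensions (dimensionless units).
SIM_FILAMENT_LENGTH = 4.0
SIM_FILAMENT_RADIUS = 0.1  # diameter 0.2
SIM_HEAD_RADIUS = 0.05  # head diameter 0.1
SIM_MOTOR_SPEED = 0.3

#: physical microtubule radius in um; carried as an annotation constant only
#: (fitted radii are PSF-inflated and an order of magnitude larger).
TRUE_MICROTUBULE_RADIUS_UM = 0.0125


class ModelValidationError(ValueError):
    """A model object violates a structural invariant."""


def _as_point(p: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ModelValidationError(f"{name}: expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ModelValidationError(f"{name}: non-finite coordinates {a}")
    return a


@dataclass
class Filament:
    """A straight polar cylinder with minus and plus ends."""

    id: str
    end_minus: np.ndarray
    end_plus: np.ndarray
    radius: float
    mass: float = 1.0
    polarity_verified: bool = True

    def __post_init__(self) -> None:
        self.end_minus = _as_point(self.end_minus, f"filament {self.id}: end_minus")
        self.end_plus = _as_point(self.end_plus, f"filament {self.id}: end_plus")

    def validate(self) -> None:
        if self.length == 0:
            raise ModelValidationError(f"filament {self.id}: end_minus == end_plus")
        if not self.radius > 0:
            raise ModelValidationError(f"filament {self.id}: radius must be > 0")
        if not self.mass > 0:
            raise ModelValidationError(f"filament {self.id}: mass must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end_plus - self.end_minus))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector pointing minus -> plus."""
        d = self.end_plus - self.end_minus
        return d / np.linalg.norm(d)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.end_minus + self.end_plus)

    def point_at_arc(self, s: float) -> np.ndarray:
        """Point at arc-length ``s`` from the minus end along the axis."""
        return self.end_minus + s * self.axis

    def end(self, label: str) -> np.ndarray:
        if label == "minus":
            return self.end_minus
        if label == "plus":
            return self.end_plus
        raise ModelValidationError(f"unknown end label {label!r}")


@dataclass
class KinesinHead:
    """One kinesin head of a multimer, attached to a filament."""

    filament_id: str
    arc: float  # arc position along the filament, measured from the minus end
    point: np.ndarray
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.point = _as_point(self.point, f"head on {self.filament_id}: point")


@dataclass
class KinesinMultimer:
    """A streptavidin-hubbed kinesin multimer bridging up to four filaments.

    The hub is the 'virtual node' coupling the head motions; each arm is a
    fixed-length tether from the hub to one head.
    """

    id: str
    hub: np.ndarray
    heads: List[KinesinHead]
    arm_length: float
    head_radius: float = SIM_HEAD_RADIUS
    motor_speed: float = SIM_MOTOR_SPEED
    hub_mass: float = 1.0

    def __post_init__(self) -> None:
        self.hub = _as_point(self.hub, f"linker {self.id}: hub")

    def validate(self, filaments: dict) -> None:
        if not 1 <= len(self.heads) <= 4:
            raise ModelValidationError(
                f"linker {self.id}: needs 1..4 heads, has {len(self.heads)}"
            )
        if not self.arm_length > 0:
            raise ModelValidationError(f"linker {self.id}: arm_length must be > 0")
        for h in self.heads:
            if h.filament_id not in filaments:
                raise ModelValidationError(
                    f"linker {self.id}: head references missing filament "
                    f"{h.filament_id!r}"
                )
            fil = filaments[h.filament_id]
            if not 0 <= h.arc <= fil.length + 1e-9:
                raise ModelValidationError(
                    f"linker {self.id}: head arc {h.arc} outside [0, {fil.length}] "
                    f"on filament {h.filament_id}"
                )


@dataclass
class Joint:
    """Ball joint: two filament ends held coincident."""

    filament_a: str
    end_a: Literal["minus", "plus"]
    filament_b: str
    end_b: Literal["minus", "plus"]
    point: np.ndarray

    def __post_init__(self) -> None:
        self.point = _as_point(self.point, "joint point")

    def validate(self, filaments: dict) -> None:
        for fid, end in ((self.filament_a, self.end_a), (self.filament_b, self.end_b)):
            if fid not in filaments:
                raise ModelValidationError(f"joint references missing filament {fid!r}")
            if end not in ("minus", "plus"):
                raise ModelValidationError(f"joint end label {end!r} invalid")


@dataclass
class FilamentNetworkModel:
    """A complete scene: filaments + kinesin multimer linkers + end joints."""

    filaments: List[Filament] = field(default_factory=list)
    linkers: List[KinesinMultimer] = field(default_factory=list)
    joints: List[Joint] = field(default_factory=list)
    units: Literal["um", "sim"] = "sim"
    max_bodies: int = MAX_BODIES

    def filament_by_id(self, fid: str) -> Filament:
        for f in self.filaments:
            if f.id == fid:
                return f
        raise KeyError(f"no filament with id {fid!r}")

    @property
    def body_count(self) -> int:
        """Rigid bodies the dynamics engine will integrate."""
        return (
            len(self.filaments)
            + sum(len(lk.heads) for lk in self.linkers)
            + len(self.linkers)  # one hub per linker
        )

    def validate(self) -> None:
        ids = [f.id for f in self.filaments]
        if len(set(ids)) != len(ids):
            raise ModelValidationError("duplicate filament ids")
        fmap = {f.id: f for f in self.filaments}
        for f in self.filaments:
            f.validate()
        for lk in self.linkers:
            lk.validate(fmap)
        for j in self.joints:
            j.validate(fmap)
        if self.units not in ("um", "sim"):
            raise ModelValidationError(f"unknown unit system {self.units!r}")
        if self.body_count > self.max_bodies:
            raise ModelValidationError(
                f"body count {self.body_count} exceeds max_bodies {self.max_bodies}"
            )


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------


def build_motility_element(
    separation: float = 0.3,
    overlap: float = 1.0,
    length: float = SIM_FILAMENT_LENGTH,
    radius: float = SIM_FILAMENT_RADIUS,
    motor_speed: float = SIM_MOTOR_SPEED,
    head_radius: float = SIM_HEAD_RADIUS,
    units: str = "sim",
    arm_length: Optional[float] = None,
    id_prefix: str = "",
) -> FilamentNetworkModel:
    """Build the minimal contraction unit: two antiparallel filaments bridged
    by a two-headed kinesin multimer.

    The filaments lie along x, offset by ``separation`` in y, with their minus
    ends at opposite outer extremes and an axial ``overlap`` (a length, in the
    same units as ``length``) around the origin.  Each head sits at the
    mid-overlap arc position of its filament; the hub sits midway between the
    heads.  Both heads walking toward their minus ends slide the filaments so
    that the overlap grows — the element contracts.
    """
    if not separation > 0:
        raise ModelValidationError("separation must be > 0")
    if not 0 < overlap <= length:
        raise ModelValidationError(f"overlap must be in (0, {length}]")
    half_sep = separation / 2.0
    if arm_length is None:
        arm_length = half_sep
    elif arm_length < half_sep:
        raise ModelValidationError(
            f"separation {separation} exceeds arm reach 2*{arm_length}"
        )
    # Filament A on +y: minus end at +x outer extreme; B mirrored.
    a = Filament(
        id=f"{id_prefix}A",
        end_minus=np.array([length - overlap / 2.0, half_sep, 0.0]),
        end_plus=np.array([-overlap / 2.0, half_sep, 0.0]),
        radius=radius,
    )
    b = Filament(
        id=f"{id_prefix}B",
        end_minus=np.array([-(length - overlap / 2.0), -half_sep, 0.0]),
        end_plus=np.array([overlap / 2.0, -half_sep, 0.0]),
        radius=radius,
    )
    arc0 = length - overlap / 2.0  # mid-overlap arc position from the minus end
    heads = [
        KinesinHead(filament_id=a.id, arc=arc0, point=a.point_at_arc(arc0)),
        KinesinHead(filament_id=b.id, arc=arc0, point=b.point_at_arc(arc0)),
    ]
    hub = 0.5 * (heads[0].point + heads[1].point)
    linker = KinesinMultimer(
        id=f"{id_prefix}K",
        hub=hub,
        heads=heads,
        arm_length=float(np.linalg.norm(heads[0].point - hub)),
        head_radius=head_radius,
        motor_speed=motor_speed,
    )
    model = FilamentNetworkModel(
        filaments=[a, b], linkers=[linker], joints=[], units=units
    )
    model.validate()
    return model


def build_aster_network(
    n_elements: int = 3,
    joint_scheme: Literal["closed", "open"] = "closed",
    separation: float = 0.3,
    overlap: float = 1.0,
    length: float = SIM_FILAMENT_LENGTH,
    radius: float = SIM_FILAMENT_RADIUS,
    motor_speed: float = SIM_MOTOR_SPEED,
    units: str = "sim",
) -> FilamentNetworkModel:
    """Chain motility elements into an aster-fragment network.

    Elements are laid along the edges of a regular polygon (``closed``) or a
    straight chain (``open``); at each shared vertex the outer (minus) ends of
    adjacent elements are tied by a ball joint.  Each filament whose minus end
    participates in a joint is tilted slightly (about 2 degrees for the
    defaults) so the joined ends coincide exactly in the initial state.
    The default ``n_elements=3`` closed ring is the three-aster-fragment
    demonstration scene.
    """
    if n_elements < 2:
        raise ModelValidationError("n_elements must be >= 2")
    if joint_scheme not in ("closed", "open"):
        raise ModelValidationError(f"unknown joint_scheme {joint_scheme!r}")
    span = 2.0 * (length - overlap / 2.0)  # outer minus-to-minus extent

    if joint_scheme == "closed":
        circum_r = span / (2.0 * math.sin(math.pi / n_elements))
        vertices = [
            np.array(
                [
                    circum_r * math.cos(2 * math.pi * k / n_elements),
                    circum_r * math.sin(2 * math.pi * k / n_elements),
                    0.0,
                ]
            )
            for k in range(n_elements)
        ]
        edges = [(k, (k + 1) % n_elements) for k in range(n_elements)]
    else:
        vertices = [np.array([span * k, 0.0, 0.0]) for k in range(n_elements + 1)]
        edges = [(k, k + 1) for k in range(n_elements)]

    filaments: List[Filament] = []
    linkers: List[KinesinMultimer] = []
    joints: List[Joint] = []
    # per-vertex record of (filament_id, "minus") ends meeting there
    vertex_ends: dict = {k: [] for k in range(len(vertices))}

    for e_idx, (k0, k1) in enumerate(edges):
        v0, v1 = vertices[k0], vertices[k1]
        ex = v1 - v0
        ex = ex / np.linalg.norm(ex)
        # in-plane normal for the lateral offset of the two filaments
        ey = np.array([-ex[1], ex[0], 0.0])
        center = 0.5 * (v0 + v1)
        half_sep = separation / 2.0
        pfx = f"e{e_idx}"
        # nominal element geometry in the edge frame (A minus toward v1)
        a_minus_n = center + (length - overlap / 2.0) * ex + half_sep * ey
        a_plus_n = center - (overlap / 2.0) * ex + half_sep * ey
        b_minus_n = center - (length - overlap / 2.0) * ex - half_sep * ey
        b_plus_n = center + (overlap / 2.0) * ex - half_sep * ey

        def _snap(minus_nominal, plus_nominal, vertex):
            """Pin the minus end on its vertex, keeping the length exact."""
            d = plus_nominal - vertex
            d = d / np.linalg.norm(d)
            return vertex, vertex + length * d

        a_minus, a_plus = _snap(a_minus_n, a_plus_n, v1)
        b_minus, b_plus = _snap(b_minus_n, b_plus_n, v0)
        a = Filament(f"{pfx}A", a_minus, a_plus, radius)
        b = Filament(f"{pfx}B", b_minus, b_plus, radius)
        arc0 = length - overlap / 2.0
        heads = [
            KinesinHead(a.id, arc0, a.point_at_arc(arc0)),
            KinesinHead(b.id, arc0, b.point_at_arc(arc0)),
        ]
        hub = 0.5 * (heads[0].point + heads[1].point)
        linkers.append(
            KinesinMultimer(
                id=f"{pfx}K",
                hub=hub,
                heads=heads,
                arm_length=float(np.linalg.norm(heads[0].point - hub)),
                motor_speed=motor_speed,
            )
        )
        filaments += [a, b]
        vertex_ends[k1].append((a.id, "minus"))
        vertex_ends[k0].append((b.id, "minus"))

    for k, ends in vertex_ends.items():
        if len(ends) == 2:
            (fa, ea), (fb, eb) = ends
            joints.append(Joint(fa, ea, fb, eb, vertices[k].copy()))

    model = FilamentNetworkModel(
        filaments=filaments, linkers=linkers, joints=joints, units=units
    )
    model.validate()
    return model


def convert_units(
    model: FilamentNetworkModel,
    to: Literal["um", "sim"],
    length_scale: float = 1.0,
) -> FilamentNetworkModel:
    """Rescale a model between microscope units (um) and simulation units.

    All positions and lengths are multiplied by ``length_scale`` (um -> sim)
    or divided by it (sim -> um).  On conversion *into* simulation units the
    filament radius is forced to the scene convention (0.1, diameter 0.2)
    regardless of the PSF-inflated fitted value; positions round-trip exactly.
    """
    if to not in ("um", "sim"):
        raise ModelValidationError(f"unknown unit system {to!r}")
    if model.units == to:
        raise ModelValidationError(f"model already in {to!r} units")
    if not length_scale > 0:
        raise ModelValidationError("length_scale must be > 0")
    s = length_scale if to == "sim" else 1.0 / length_scale

    def scale_fil(f: Filament) -> Filament:
        radius = SIM_FILAMENT_RADIUS if to == "sim" else f.radius * s
        return replace(
            f, end_minus=f.end_minus * s, end_plus=f.end_plus * s, radius=radius
        )

    def scale_linker(lk: KinesinMultimer) -> KinesinMultimer:
        heads = [
            replace(h, arc=h.arc * s, point=h.point * s) for h in lk.heads
        ]
        return replace(
            lk,
            hub=lk.hub * s,
            heads=heads,
            arm_length=lk.arm_length * s,
            head_radius=lk.head_radius * s,
        )

    out = FilamentNetworkModel(
        filaments=[scale_fil(f) for f in model.filaments],
        linkers=[scale_linker(lk) for lk in model.linkers],
        joints=[replace(j, point=j.point * s) for j in model.joints],
        units=to,
        max_bodies=model.max_bodies,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FIL_FIELDS = {"id", "end_minus", "end_plus", "radius", "mass", "polarity_verified"}
_HEAD_FIELDS = {"filament", "arc", "point", "mass"}
_LINKER_FIELDS = {
    "id",
    "hub",
    "heads",
    "arm_length",
    "head_radius",
    "motor_speed",
    "hub_mass",
}
_JOINT_FIELDS = {"filament_a", "end_a", "filament_b", "end_b", "point"}
_TOP_FIELDS = {"schema", "units", "filaments", "linkers", "joints", "max_bodies"}


class ModelSchemaError(ModelValidationError):
    """The JSON document does not match the network-model schema."""


def _check_fields(obj: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ModelSchemaError(f"{where}: unknown fields {sorted(unknown)}")
    missing = required - set(obj)
    if missing:
        raise ModelSchemaError(f"{where}: missing fields {sorted(missing)}")


def model_to_dict(model: FilamentNetworkModel) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "units": model.units,
        "max_bodies": model.max_bodies,
        "filaments": [
            {
                "id": f.id,
                "end_minus": f.end_minus.tolist(),
                "end_plus": f.end_plus.tolist(),
                "radius": f.radius,
                "mass": f.mass,
                "polarity_verified": f.polarity_verified,
            }
            for f in model.filaments
        ],
        "linkers": [
            {
                "id": lk.id,
                "hub": lk.hub.tolist(),
                "arm_length": lk.arm_length,
                "head_radius": lk.head_radius,
                "motor_speed": lk.motor_speed,
                "hub_mass": lk.hub_mass,
                "heads": [
                    {
                        "filament": h.filament_id,
                        "arc": h.arc,
                        "point": h.point.tolist(),
                        "mass": h.mass,
                    }
                    for h in lk.heads
                ],
            }
            for lk in model.linkers
        ],
        "joints": [
            {
                "filament_a": j.filament_a,
                "end_a": j.end_a,
                "filament_b": j.filament_b,
                "end_b": j.end_b,
                "point": j.point.tolist(),
            }
            for j in model.joints
        ],
    }


def model_from_dict(doc: dict) -> FilamentNetworkModel:
    if not isinstance(doc, dict):
        raise ModelSchemaError("document root must be an object")
    _check_fields(doc, _TOP_FIELDS, {"schema", "units", "filaments"}, "root")
    if doc["schema"] != MODEL_SCHEMA:
        raise ModelSchemaError(f"unknown schema {doc['schema']!r}")
    filaments = []
    for i, fd in enumerate(doc["filaments"]):
        _check_fields(
            fd, _FIL_FIELDS, {"id", "end_minus", "end_plus", "radius"}, f"filaments[{i}]"
        )
        filaments.append(
            Filament(
                id=fd["id"],
                end_minus=np.array(fd["end_minus"], dtype=float),
                end_plus=np.array(fd["end_plus"], dtype=float),
                radius=float(fd["radius"]),
                mass=float(fd.get("mass", 1.0)),
                polarity_verified=bool(fd.get("polarity_verified", True)),
            )
        )
    linkers = []
    for i, ld in enumerate(doc.get("linkers", [])):
        _check_fields(
            ld, _LINKER_FIELDS, {"id", "hub", "heads", "arm_length"}, f"linkers[{i}]"
        )
        heads = []
        for k, hd in enumerate(ld["heads"]):
            _check_fields(
                hd, _HEAD_FIELDS, {"filament", "arc", "point"}, f"linkers[{i}].heads[{k}]"
            )
            heads.append(
                KinesinHead(
                    filament_id=hd["filament"],
                    arc=float(hd["arc"]),
                    point=np.array(hd["point"], dtype=float),
                    mass=float(hd.get("mass", 1.0)),
                )
            )
        linkers.append(
            KinesinMultimer(
                id=ld["id"],
                hub=np.array(ld["hub"], dtype=float),
                heads=heads,
                arm_length=float(ld["arm_length"]),
                head_radius=float(ld.get("head_radius", SIM_HEAD_RADIUS)),
                motor_speed=float(ld.get("motor_speed", SIM_MOTOR_SPEED)),
                hub_mass=float(ld.get("hub_mass", 1.0)),
            )
        )
    joints = []
    for i, jd in enumerate(doc.get("joints", [])):
        _check_fields(jd, _JOINT_FIELDS, _JOINT_FIELDS, f"joints[{i}]")
        joints.append(
            Joint(
                filament_a=jd["filament_a"],
                end_a=jd["end_a"],
                filament_b=jd["filament_b"],
                end_b=jd["end_b"],
                point=np.array(jd["point"], dtype=float),
            )
        )
    model = FilamentNetworkModel(
        filaments=filaments,
        linkers=linkers,
        joints=joints,
        units=doc["units"],
        max_bodies=int(doc.get("max_bodies", MAX_BODIES)),
    )
    model.validate()
    return model


def write_model(model: FilamentNetworkModel, path) -> None:
    model.validate()
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def read_model(path) -> FilamentNetworkModel:
    with open(path) as fh:
        doc = json.load(fh)
    return model_from_dict(doc)


def filament_table(model: FilamentNetworkModel, residuals=None) -> pd.DataFrame:
    """One row per filament: endpoints, radius, length (plus fit residual)."""
    rows = []
    for f in model.filaments:
        row = {
            "id": f.id,
            "minus_x": f.end_minus[0],
            "minus_y": f.end_minus[1],
            "minus_z": f.end_minus[2],
            "plus_x": f.end_plus[0],
            "plus_y": f.end_plus[1],
            "plus_z": f.end_plus[2],
            "radius": f.radius,
            "length": f.length,
        }
        if residuals is not None:
            row["residual"] = residuals.get(f.id, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def export_obj(model: FilamentNetworkModel, path, sections: int = 16) -> None:
    """Export the scene as a Wavefront OBJ (cylinders + spheres) for viewing."""
    import trimesh

    meshes = []
    for f in model.filaments:
        seg = np.vstack([f.end_minus, f.end_plus])
        meshes.append(
            trimesh.creation.cylinder(radius=f.radius, segment=seg, sections=sections)
        )
    for lk in model.linkers:
        for h in lk.heads:
            sph = trimesh.creation.icosphere(subdivisions=1, radius=lk.head_radius)
            sph.apply_translation(h.point)
            meshes.append(sph)
        hub = trimesh.creation.icosphere(subdivisions=1, radius=lk.head_radius)
        hub.apply_translation(lk.hub)
        meshes.append(hub)
    if not meshes:
        raise ModelValidationError("empty model: nothing to export")
    trimesh.util.concatenate(meshes).export(path, file_type="obj")
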