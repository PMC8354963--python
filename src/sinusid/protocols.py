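"""The four reference-model protocols (groups A-D) for one mesh pair.

Both steps of a 3D-3D superimposition need a reference ("master") model:
registration moves the other ("slave") model onto it, and the distance
calculation measures how far one model's surface sits from it. With two
models per comparison this gives four protocols:

=====  ======================  ====================
group  registration reference  distance reference
=====  ======================  ====================
A      sample 1                sample 2
B      sample 1                sample 1
C      sample 2                sample 1
D      sample 2                sample 2
=====  ======================  ====================

The query mesh of the distance step is always the model that is *not* the
distance reference, after registration. Within one quartet the registration
with a given reference is computed once and shared between the two groups
that use it ({A, B} and {C, D}), so that swapping the distance reference
isolates exactly one factor; set ``share_registration=False`` to re-run the
registration independently per group.

Protocol RMS values are reported at the 0.01 mm resolution used by 3D
comparison software (and by the study tables this pipeline replicates);
pass ``rms_resolution_mm=None`` for full floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .distance import NearestSurface, nearest_point_distances
from .mesh import measure
from .registration import RegistrationReport, icp_register

__all__ = ["ProtocolSpec", "PROTOCOLS", "ICPParams", "ProtocolQuartet",
           "RMS_RESOLUTION_MM", "run_protocol", "run_quartet"]


@dataclass(frozen=True)
class ProtocolSpec:
    """One of the four (registration reference, distance reference) choices."""

    label: str
    registration_reference: int  # 1 or 2
    distance_reference: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.registration_reference not in (1, 2) or self.distance_reference not in (1, 2):
            raise ValueError("references must be sample 1 or 2")


PROTOCOLS: dict[str, ProtocolSpec] = {
    "A": ProtocolSpec("A", registration_reference=1, distance_reference=2),
    "B": ProtocolSpec("B", registration_reference=1, distance_reference=1),
    "C": ProtocolSpec("C", registration_reference=2, distance_reference=1),
    "D": ProtocolSpec("D", registration_reference=2, distance_reference=2),
}


RMS_RESOLUTION_MM = 0.01


def _round_rms(value: float, resolution: float | None) -> float:
    if resolution is None:
        return value
    return round(round(value / resolution) * resolution, 10)


@dataclass(frozen=True)
class ICPParams:
    max_iterations: int = 100
    tolerance_mm: float = 1e-6
    sample_size: int | None = None
    seed: int = 0


@dataclass
class ProtocolQuartet:
    """RMS of all four protocols for one pair, with derived deltas.

    ``registration_deltas`` (|B-C|, |A-D|) isolate the registration
    reference swap; ``calculation_deltas`` (|A-B|, |C-D|) isolate the
    distance-reference swap. ``size_deltas`` are absolute differences of the
    two models' breadth (mm), height (mm) and volume (cm^3).
    """

    pair_id: str
    is_match: bool
    rms: dict[str, float]
    registration_deltas: dict[str, float] = field(default_factory=dict)
    calculation_deltas: dict[str, float] = field(default_factory=dict)
    size_deltas: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        r = self.rms
        if not self.registration_deltas:
            self.registration_deltas = {
                "B-C": abs(r["B"] - r["C"]),
                "A-D": abs(r["A"] - r["D"]),
            }
        if not self.calculation_deltas:
            self.calculation_deltas = {
                "A-B": abs(r["A"] - r["B"]),
                "C-D": abs(r["C"] - r["D"]),
            }

    def to_row(self) -> dict[str, float | str | bool]:
        row: dict[str, float | str | bool] = {"pair_id": self.pair_id, "is_match": self.is_match}
        row.update({f"rms_{g}": self.rms[g] for g in "ABCD"})
        row.update({f"delta_{k}": v for k, v in self.registration_deltas.items()})
        row.update({f"delta_{k}": v for k, v in self.calculation_deltas.items()})
        row.update({f"delta_{k}": v for k, v in self.size_deltas.items()})
        row["converged"] = self.converged
        return row


def _registrations(
    model1: trimesh.Trimesh,
    model2: trimesh.Trimesh,
    surf1: NearestSurface,
    surf2: NearestSurface,
    params: ICPParams,
    which: set[int],
) -> dict[int, RegistrationReport]:
    """ICP of the non-reference model onto each requested reference."""
    out = {}
    if 1 in which:
        out[1] = icp_register(
            model2, model1, surface=surf1,
            max_iterations=params.max_iterations, tolerance_mm=params.tolerance_mm,
            sample_size=params.sample_size, seed=params.seed,
        )
    if 2 in which:
        out[2] = icp_register(
            model1, model2, surface=surf2,
            max_iterations=params.max_iterations, tolerance_mm=params.tolerance_mm,
            sample_size=params.sample_size, seed=params.seed,
        )
    return out


def _protocol_rms(
    label: str,
    model1: trimesh.Trimesh,
    model2: trimesh.Trimesh,
    surf1: NearestSurface,
    surf2: NearestSurface,
    regs: dict[int, RegistrationReport],
) -> float:
    """RMS for one group given the shared registrations.

    Distances are evaluated in the distance reference's own frame: measuring
    from a static query mesh to a *moved* reference surface is identical to
    measuring from the inverse-moved query mesh to the static surface, which
    lets one spatial index per mesh serve all four groups.
    """
    spec = PROTOCOLS[label]
    T = regs[spec.registration_reference].transform
    v1 = model1.vertices.view(np.ndarray)
    v2 = model2.vertices.view(np.ndarray)
    if spec.registration_reference == 1:
        moved2 = T.apply(v2)
        if spec.distance_reference == 1:  # B: moved model 2 vs surface 1
            return nearest_point_distances(moved2, surf1, signed=False).rms
        # A: model 1 vs moved model 2 == inverse-moved model 1 vs surface 2
        return nearest_point_distances(T.inverse().apply(v1), surf2, signed=False).rms
    moved1 = T.apply(v1)
    if spec.distance_reference == 2:  # D: moved model 1 vs surface 2
        return nearest_point_distances(moved1, surf2, signed=False).rms
    # C: model 2 vs moved model 1 == inverse-moved model 2 vs surface 1
    return nearest_point_distances(T.inverse().apply(v2), surf1, signed=False).rms


def run_protocol(
    model1: trimesh.Trimesh,
    model2: trimesh.Trimesh,
    spec: ProtocolSpec | str,
    params: ICPParams | None = None,
    *,
    surfaces: tuple[NearestSurface, NearestSurface] | None = None,
    registrations: dict[int, RegistrationReport] | None = None,
    rms_resolution_mm: float | None = RMS_RESOLUTION_MM,
) -> float:
    """RMS point-to-point distance (mm) for one protocol on one pair."""
    label = spec if isinstance(spec, str) else spec.label
    if label not in PROTOCOLS:
        raise ValueError(f"unknown protocol {label!r}; expected A, B, C or D")
    params = params or ICPParams()
    surf1, surf2 = surfaces if surfaces is not None else (NearestSurface(model1), NearestSurface(model2))
    ref = PROTOCOLS[label].registration_reference
    regs = registrations if registrations is not None else _registrations(
        model1, model2, surf1, surf2, params, {ref}
    )
    return _round_rms(_protocol_rms(label, model1, model2, surf1, surf2, regs),
                      rms_resolution_mm)


def run_quartet(
    model1: trimesh.Trimesh,
    model2: trimesh.Trimesh,
    params: ICPParams | None = None,
    *,
    pair_id: str = "",
    is_match: bool = True,
    surfaces: tuple[NearestSurface, NearestSurface] | None = None,
    share_registration: bool = True,
    with_sizes: bool = True,
    rms_resolution_mm: float | None = RMS_RESOLUTION_MM,
) -> ProtocolQuartet:
    """Run all four protocols on one pair and assemble the quartet."""
    params = params or ICPParams()
    surf1, surf2 = surfaces if surfaces is not None else (NearestSurface(model1), NearestSurface(model2))
    regs = _registrations(model1, model2, surf1, surf2, params, {1, 2})
    converged = all(r.converged for r in regs.values())
    rms: dict[str, float] = {}
    for label in "ABCD":
        use = regs if share_registration else _registrations(
            model1, model2, surf1, surf2, params, {PROTOCOLS[label].registration_reference}
        )
        rms[label] = _round_rms(
            _protocol_rms(label, model1, model2, surf1, surf2, use), rms_resolution_mm
        )
    size_deltas: dict[str, float] = {}
    if with_sizes:
        s1 = measure(model1)
        s2 = measure(model2)
        size_deltas = {
            "breadth": abs(s1.breadth - s2.breadth),
            "height": abs(s1.height - s2.height),
            "volume": abs(s1.volume - s2.volume),
        }
    return ProtocolQuartet(
        pair_id=pair_id,
        is_match=is_match,
        rms=rms,
        size_deltas=size_deltas,
        converged=converged,
    )
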