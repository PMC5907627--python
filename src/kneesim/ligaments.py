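"""Knee ligaments as tension-only piecewise quadratic-linear springs.

Each bundle is a straight line element between an origin and an insertion on
two different bodies.  The constitutive law is the standard quadratic-toe /
linear law used throughout the knee-modelling literature: with strain
``e = (L - L0)/L0`` and toe strain ``e_t``,

    f(e) = 0                      e <= 0
    f(e) = k * e^2 / (4 e_t)      0 < e < 2 e_t
    f(e) = k * (e - e_t)          e >= 2 e_t

``k`` is the linear-region stiffness in newtons per unit strain.  The law is
C1-continuous, which the equilibrium solver relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from io import StringIO

import numpy as np
import pandas as pd

__all__ = [
    "LIGAMENT_NAMES",
    "LigamentBundle",
    "ligament_force",
    "ligament_energy",
    "ligaments_to_csv",
    "ligaments_from_csv",
]

# The seven soft-tissue structures restraining the CR-TKA knee (the PCL is
# retained and split into anterolateral and posteromedial bundles), plus the
# extensor-apparatus ligaments.
LIGAMENT_NAMES = ("MCL", "LCL", "PCL_AL", "PCL_PM", "MPFL", "PL", "ALC", "PC")

_BODIES = ("femur", "tibia", "patella")


@dataclass(frozen=True)
class LigamentBundle:
    """One ligament bundle.

    origin/insertion are (3,) positions in the frame of origin_body /
    insertion_body.  ``slack_length`` L0 (m), ``stiffness`` k (N per unit
    strain), ``toe_strain`` e_t (dimensionless), and the reference strain at
    full extension used to calibrate L0.
    """

    name: str
    origin_body: str
    origin: np.ndarray
    insertion_body: str
    insertion: np.ndarray
    slack_length: float
    stiffness: float
    toe_strain: float
    reference_strain: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, float).reshape(3))
        if self.origin_body not in _BODIES or self.insertion_body not in _BODIES:
            raise ValueError(f"bodies must be in {_BODIES}")
        if self.slack_length <= 0:
            raise ValueError("slack length must be positive")
        if self.stiffness < 0 or self.toe_strain < 0:
            raise ValueError("stiffness and toe strain must be non-negative")

    def with_slack_length(self, L0: float) -> "LigamentBundle":
        return replace(self, slack_length=L0)


def ligament_force(length: float, bundle: LigamentBundle) -> float:
    """Tension (N, >= 0) of a bundle at the given end-to-end length (m)."""
    if not np.isfinite(length):
        raise ValueError("non-finite ligament length")
    if length <= 0:
        raise ValueError("ligament length must be positive")
    e = (length - bundle.slack_length) / bundle.slack_length
    k, et = bundle.stiffness, bundle.toe_strain
    if e <= 0.0:
        return 0.0
    if et > 0.0 and e < 2.0 * et:
        return k * e * e / (4.0 * et)
    return k * (e - et)


def ligament_energy(length: float, bundle: LigamentBundle) -> float:
    """Stored elastic energy (J); its length-derivative is ligament_force."""
    if length <= 0 or not np.isfinite(length):
        raise ValueError("invalid ligament length")
    L0 = bundle.slack_length
    e = (length - L0) / L0
    k, et = bundle.stiffness, bundle.toe_strain
    if e <= 0.0:
        return 0.0
    if et > 0.0 and e < 2.0 * et:
        # integral of k e^2/(4 et) dL = L0 * k e^3 / (12 et)
        return L0 * k * e**3 / (12.0 * et)
    toe = L0 * k * (2.0 * et) ** 3 / (12.0 * et) if et > 0.0 else 0.0
    return toe + L0 * 0.5 * k * ((e - et) ** 2 - et**2)


_CSV_COLUMNS = [
    "name",
    "origin_body",
    "origin_x",
    "origin_y",
    "origin_z",
    "insertion_body",
    "insertion_x",
    "insertion_y",
    "insertion_z",
    "slack_length",
    "stiffness",
    "toe_strain",
    "reference_strain",
]


def ligaments_to_csv(bundles: list[LigamentBundle]) -> str:
    """Serialize a ligament parameter table to CSV text."""
    rows = []
    for b in bundles:
        rows.append(
            {
                "name": b.name,
                "origin_body": b.origin_body,
                "origin_x": b.origin[0],
                "origin_y": b.origin[1],
                "origin_z": b.origin[2],
                "insertion_body": b.insertion_body,
                "insertion_x": b.insertion[0],
                "insertion_y": b.insertion[1],
                "insertion_z": b.insertion[2],
                "slack_length": b.slack_length,
                "stiffness": b.stiffness,
                "toe_strain": b.toe_strain,
                "reference_strain": b.reference_strain,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(index=False)


def ligaments_from_csv(text: str) -> list[LigamentBundle]:
    df = pd.read_csv(StringIO(text))
    out = []
    for _, r in df.iterrows():
        out.append(
            LigamentBundle(
                name=str(r["name"]),
                origin_body=str(r["origin_body"]),
                origin=np.array([r["origin_x"], r["origin_y"], r["origin_z"]]),
                insertion_body=str(r["insertion_body"]),
                insertion=np.array([r["insertion_x"], r["insertion_y"], r["insertion_z"]]),
                slack_length=float(r["slack_length"]),
                stiffness=float(r["stiffness"]),
                toe_strain=float(r["toe_strain"]),
                reference_strain=float(r["reference_strain"]),
            )
        )
    return out
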