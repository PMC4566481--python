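"""Candidate-model family for radiation-induced DNA damage foci kinetics.

The family extends the classical two-lesion kinetic (TLK) picture — simple
and complex double-strand breaks (DSBs) repaired at fast and slow rates —
with two additional damage categories: persistent telomere-associated foci
(TAF), which are not repaired on the time scales considered, and a constant
basal background signal ``B``.  Structural options (repair-protein binding,
a second-order "binary misrepair" channel, backward dissociation of
protein-bound breaks, and a linear vs square-root dose mapping) combine into
exactly 20 legal variants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Optional

__all__ = [
    "ProteinBinding",
    "DoseMap",
    "ModelVariant",
    "ParameterSet",
    "enumerate_variants",
    "get_variant",
    "parameter_names",
    "FIXED_PROTEIN_POOL",
]

#: Repair-protein pool size (focus equivalents) used when the pool is fixed
#: rather than fitted; the value adopted by the published reference models.
FIXED_PROTEIN_POOL = 20.0


class ProteinBinding(str, enum.Enum):
    """Whether repair-protein binding is modelled, and how the pool is set."""

    NONE = "none"       # DSBs repaired directly, first order
    FIXED = "fixed"     # protein pool fixed at FIXED_PROTEIN_POOL
    FREE = "free"       # protein pool P_total is a fitted parameter


class DoseMap(str, enum.Enum):
    """Mapping from absorbed dose D (Gy) to induced-damage units."""

    LINEAR = "linear"
    SQRT = "sqrt"


@dataclass(frozen=True)
class ModelVariant:
    """Structural flags defining one candidate model.

    Attributes
    ----------
    variant_id : int
        Identifier 1-20 matching the published model numbering.
    protein_binding : ProteinBinding
        Direct repair (``none``) or repair through protein-bound complexes
        with a fixed or fitted protein pool.
    second_order : bool
        Include the binary-misrepair channel ``kcross * (Si + Ci)``.
    backward : bool
        Include dissociation of protein-bound breaks (rates k2, k4).  Only
        legal when protein binding is modelled.
    dose_map : DoseMap
        Linear or square-root dose-to-damage mapping.
    """

    variant_id: int
    protein_binding: ProteinBinding
    second_order: bool
    backward: bool
    dose_map: DoseMap

    def __post_init__(self) -> None:
        if self.backward and self.protein_binding is ProteinBinding.NONE:
            raise ValueError(
                "backward reactions (k2, k4) require protein binding"
            )
        if not 1 <= self.variant_id <= 20:
            raise ValueError(f"variant_id must be 1-20, got {self.variant_id}")

    @property
    def has_protein(self) -> bool:
        return self.protein_binding is not ProteinBinding.NONE

    @property
    def n_parameters(self) -> int:
        """Number of free parameters implied by the structural flags."""
        return len(parameter_names(self))

    @property
    def k(self) -> int:  # conventional symbol in information criteria
        return self.n_parameters


#: Base parameters shared by every variant: induced foci per dose unit,
#: complex fraction, the two initial repair/binding rates, TAF induction,
#: background TAF and basal background foci.
_BASE_PARAMS = ("kDSB", "c", "k1", "k3", "kTAF", "T0", "B")


def parameter_names(variant: ModelVariant) -> tuple[str, ...]:
    """Ordered free-parameter names for *variant*.

    The count reproduces the published k column for all 20 variants
    (7 for the simplest, 13 for the fullest model).
    """
    names = list(_BASE_PARAMS)
    if variant.second_order:
        names.append("kcross")
    if variant.has_protein:
        names += ["kf", "ks"]
    if variant.backward:
        names += ["k2", "k4"]
    if variant.protein_binding is ProteinBinding.FREE:
        names.append("P_total")
    return tuple(names)


# variant_id -> (protein_binding, second_order, backward, dose_map),
# matching the published model numbering.
_VARIANT_FLAGS: dict[int, tuple[ProteinBinding, bool, bool, DoseMap]] = {
    1: (ProteinBinding.FIXED, True, True, DoseMap.LINEAR),
    2: (ProteinBinding.FIXED, True, True, DoseMap.SQRT),
    3: (ProteinBinding.FIXED, False, True, DoseMap.LINEAR),
    4: (ProteinBinding.FIXED, False, True, DoseMap.SQRT),
    5: (ProteinBinding.NONE, True, False, DoseMap.LINEAR),
    6: (ProteinBinding.NONE, True, False, DoseMap.SQRT),
    7: (ProteinBinding.NONE, False, False, DoseMap.LINEAR),
    8: (ProteinBinding.NONE, False, False, DoseMap.SQRT),
    9: (ProteinBinding.FIXED, True, False, DoseMap.LINEAR),
    10: (ProteinBinding.FIXED, True, False, DoseMap.SQRT),
    11: (ProteinBinding.FIXED, False, False, DoseMap.LINEAR),
    12: (ProteinBinding.FIXED, False, False, DoseMap.SQRT),
    13: (ProteinBinding.FREE, True, True, DoseMap.LINEAR),
    14: (ProteinBinding.FREE, True, True, DoseMap.SQRT),
    15: (ProteinBinding.FREE, False, True, DoseMap.LINEAR),
    16: (ProteinBinding.FREE, False, True, DoseMap.SQRT),
    17: (ProteinBinding.FREE, True, False, DoseMap.LINEAR),
    18: (ProteinBinding.FREE, True, False, DoseMap.SQRT),
    19: (ProteinBinding.FREE, False, False, DoseMap.LINEAR),
    20: (ProteinBinding.FREE, False, False, DoseMap.SQRT),
}


def get_variant(variant_id: int) -> ModelVariant:
    """Return the :class:`ModelVariant` with the given published id."""
    try:
        pb, so, bw, dm = _VARIANT_FLAGS[variant_id]
    except KeyError:
        raise ValueError(
            f"unknown variant_id {variant_id!r}; legal ids are 1-20"
        ) from None
    return ModelVariant(variant_id, pb, so, bw, dm)


def enumerate_variants() -> list[ModelVariant]:
    """All 20 candidate models, ordered by variant_id."""
    return [get_variant(i) for i in sorted(_VARIANT_FLAGS)]


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and dose coefficients for one model variant.

    Units: rates are day^-1 (k1/k3 are per-focus day^-1 in protein variants,
    where they act as binding coefficients multiplied by the free pool P);
    kcross is per-focus day^-1; kDSB and kTAF are induced foci per dose unit
    (per Gy for a linear dose map, per sqrt-Gy for a square-root map); c is
    the dimensionless complex fraction in [0, 1]; T0, B are foci per cell;
    P_total is the protein pool in focus equivalents.

    Fields a variant does not use may be left ``None``; the dynamics only
    ever read the fields the variant declares.
    """

    kDSB: Optional[float] = None
    c: Optional[float] = None
    k1: Optional[float] = None
    k3: Optional[float] = None
    kTAF: Optional[float] = None
    T0: Optional[float] = None
    B: Optional[float] = None
    kcross: Optional[float] = None
    kf: Optional[float] = None
    ks: Optional[float] = None
    k2: Optional[float] = None
    k4: Optional[float] = None
    P_total: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.c is not None and self.c > 1:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")

    def get(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise KeyError(f"parameter {name!r} is not set")
        return float(v)

    def validate_for(self, variant: ModelVariant) -> None:
        """Raise if any parameter the variant needs is missing."""
        missing = [n for n in parameter_names(variant)
                   if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"variant {variant.variant_id} requires parameters "
                f"{missing} which are not set"
            )

    def to_vector(self, variant: ModelVariant):
        """Free parameters in the variant's canonical order."""
        self.validate_for(variant)
        return [self.get(n) for n in parameter_names(variant)]

    @classmethod
    def from_vector(cls, variant: ModelVariant, values) -> "ParameterSet":
        names = parameter_names(variant)
        if len(values) != len(names):
            raise ValueError(
                f"expected {len(names)} values for variant "
                f"{variant.variant_id}, got {len(values)}"
            )
        return cls(**dict(zip(names, map(float, values))))

    def to_dict(self) -> dict[str, float]:
        return {
            f.name: float(getattr(self, f.name))
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    def protein_pool(self, variant: ModelVariant) -> float:
        """Initial repair-protein pool for a protein variant."""
        if not variant.has_protein:
            raise ValueError("no-protein variant has no protein pool")
        if variant.protein_binding is ProteinBinding.FIXED:
            return FIXED_PROTEIN_POOL
        return self.get("P_total")
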