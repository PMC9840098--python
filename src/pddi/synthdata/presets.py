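"""Built-in dataset specifications for the two study conditions.

The colorectal pair (2000 screenings vs 17,866 registrations, 60 planted
common persons) carries errors on 51 of the 60 common records, 25 of them
on multiple matching keys; the breast pair (1048 vs 29,949, 62 common)
perturbs 36 of 62 with 14 multi-key records and an all-female population.
Error rates are deliberately far above what registry managers expect of
real Japanese data (<10-15%), making these worst-case matching conditions.
"""

from __future__ import annotations

from .errors import ErrorCategory as C
from .errors import RowAttr as A
from .pairs import DatasetSpec
from .plan import ErrorPlan

__all__ = ["COLORECTAL_PLAN", "BREAST_PLAN", "preset_spec", "PRESETS"]

COLORECTAL_PLAN = ErrorPlan(
    counts=(
        (C.typing, A.name, 3),
        (C.typing, A.birth_date, 15),
        (C.typing, A.address, 6),
        (C.typing, A.sex, 5),
        (C.kanji_conversion, A.name, 5),
        (C.kanji_conversion, A.address, 2),
        (C.misreading, A.name, 10),
        (C.missing_letter, A.name, 2),
        (C.omission, A.address, 4),
        (C.omission, A.name, 10),
        (C.variant_kanji, A.name, 7),
        (C.address_format, A.address, 5),
        (C.name_change, A.name, 2),
        (C.alias, A.name, 2),
        (C.moving, A.address, 2),
    ),
    multi_key=25,
    total=51,
)

BREAST_PLAN = ErrorPlan(
    counts=(
        (C.typing, A.name, 1),
        (C.typing, A.address, 2),
        (C.kanji_conversion, A.name, 6),
        (C.misreading, A.name, 8),
        (C.missing_letter, A.name, 1),
        (C.omission, A.name, 1),
        (C.variant_kanji, A.name, 4),
        (C.address_format, A.address, 15),
        (C.name_change, A.name, 1),
        (C.moving, A.address, 8),
    ),
    multi_key=14,
    total=36,
)

PRESETS = ("colorectal", "breast")


def preset_spec(name: str, seed: int = 0, scale: float = 1.0) -> DatasetSpec:
    """A built-in study condition, optionally scaled down in dataset size.

    ``scale`` shrinks the screening/registry sizes (never the planted
    common subset or its error plan) for quick runs.
    """
    if name == "colorectal":
        n_s, n_r, n_c = 2000, 17_866, 60
        plan, sex = COLORECTAL_PLAN, None
    elif name == "breast":
        n_s, n_r, n_c = 1048, 29_949, 62
        plan, sex = BREAST_PLAN, "F"
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    if scale != 1.0:
        n_s = max(n_c, int(round(n_s * scale)))
        n_r = max(n_c, int(round(n_r * scale)))
    return DatasetSpec(
        n_screening=n_s,
        n_registry=n_r,
        n_common=n_c,
        cancer_type=name,
        error_plan=plan,
        seed=seed,
        sex=sex,
    )
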