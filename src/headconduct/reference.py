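"""Recommended tissue-conductivity reference values for head modelling.

Packages the quality-weighted mean conductivities from the meta-analytic
synthesis as a citable lookup for EEG/MEG volume-conductor construction:
scalp 0.41 S/m, whole skull 0.02 S/m (or spongiform 0.048 / inner compact
0.007 / outer compact 0.005 S/m for a three-layer skull), CSF 1.71 S/m,
grey matter 0.47 S/m, white matter 0.22 S/m and a brain-to-skull
conductivity ratio of 50.4, among others.  The table is shipped as data
(JSON), never hard-coded in logic.

Also provides dispersion-aware sampling of plausible individual values —
a truncated log-normal matched to each entry's mean and SD — for
sensitivity studies of forward/inverse solutions.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .corpus import TissueLabel

__all__ = [
    "ReferenceError",
    "ReferenceEntry",
    "SkullMode",
    "BrainMode",
    "WhiteMatterMode",
    "HeadProfile",
    "load_reference_table",
    "recommended",
    "build_head_profile",
    "sample_individual",
]


class ReferenceError(KeyError):
    pass


@dataclass(frozen=True)
class ReferenceEntry:
    """One tissue's recommended value: weighted mean ± SD in S/m
    (dimensionless for the brain-to-skull ratio), with the observed
    min/max of the synthesis as truncation bounds."""

    tissue: TissueLabel
    weighted_mean: float
    sd: float | None
    minimum: float
    maximum: float
    n_values: int
    n_studies: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.weighted_mean <= self.maximum):
            raise ValueError(
                f"{self.tissue}: weighted mean {self.weighted_mean} outside "
                f"[{self.minimum}, {self.maximum}]"
            )
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"{self.tissue}: negative sd")

    def as_dict(self) -> dict:
        return {
            "tissue": str(self.tissue),
            "weighted_mean": self.weighted_mean,
            "sd": self.sd,
            "minimum": self.minimum,
            "maximum": self.maximum,
            "n_values": self.n_values,
            "n_studies": self.n_studies,
        }


def _entries_from_payload(payload: dict) -> dict[str, ReferenceEntry]:
    table: dict[str, ReferenceEntry] = {}
    for raw in payload["entries"]:
        entry = ReferenceEntry(
            tissue=TissueLabel.from_name(raw["tissue"]),
            weighted_mean=float(raw["weighted_mean"]),
            sd=None if raw["sd"] is None else float(raw["sd"]),
            minimum=float(raw["minimum"]),
            maximum=float(raw["maximum"]),
            n_values=int(raw["n_values"]),
            n_studies=int(raw["n_studies"]),
        )
        table[str(entry.tissue)] = entry
    return table


def load_reference_table(path: str | Path | None = None) -> dict[str, ReferenceEntry]:
    """The packaged reference table (or a user-supplied one), keyed by
    tissue name."""
    if path is None:
        text = resources.files("headconduct.data").joinpath(
            "reference_values.json"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return _entries_from_payload(json.loads(text))


def save_reference_table(table: dict[str, ReferenceEntry], path: str | Path) -> None:
    payload = {
        "name": "head-conductivity-reference-v1",
        "entries": [table[k].as_dict() for k in table],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def recommended(tissue: TissueLabel | str) -> ReferenceEntry:
    """The packaged entry for one tissue, verbatim."""
    table = load_reference_table()
    key = str(tissue) if isinstance(tissue, TissueLabel) else str(tissue).strip().lower()
    # "scalp" is accepted as shorthand for the whole-scalp entry.
    aliases = {"scalp": "whole_scalp", "skull": "whole_skull", "brain": "whole_brain"}
    key = aliases.get(key, key)
    if key not in table:
        raise ReferenceError(
            f"no reference entry for {key!r}; available: {', '.join(sorted(table))}"
        )
    return table[key]


class SkullMode(str, enum.Enum):
    WHOLE = "whole"
    THREE_LAYER = "three_layer"


class BrainMode(str, enum.Enum):
    WHOLE = "whole"
    GM_WM = "gm_wm"


class WhiteMatterMode(str, enum.Enum):
    ISOTROPIC = "isotropic"      # single WM value
    ANISOTROPIC = "anisotropic"  # parallel / perpendicular pair


@dataclass(frozen=True)
class HeadProfile:
    """Layer → conductivity map for one compartmentalisation choice."""

    layers: dict[str, float]
    skull_mode: SkullMode
    brain_mode: BrainMode
    wm_mode: WhiteMatterMode = WhiteMatterMode.ISOTROPIC

    def as_dict(self) -> dict:
        return dict(self.layers)


def build_head_profile(
    skull_mode: SkullMode | str = SkullMode.WHOLE,
    brain_mode: BrainMode | str = BrainMode.GM_WM,
    wm_mode: WhiteMatterMode | str = WhiteMatterMode.ISOTROPIC,
    include_csf: bool = True,
) -> HeadProfile:
    """Assemble a layer → σ map from the packaged entries.

    ``skull_mode="whole"`` uses the homogeneous whole-skull value;
    ``"three_layer"`` uses spongiform / inner compact / outer compact
    (the two choices are mutually exclusive by construction).  The white
    matter representation — single isotropic value or the parallel/
    perpendicular pair — is an explicit choice, never defaulted silently
    to one of the anisotropic values.
    """
    skull_mode = SkullMode(skull_mode)
    brain_mode = BrainMode(brain_mode)
    wm_mode = WhiteMatterMode(wm_mode)
    layers: dict[str, float] = {"scalp": recommended("whole_scalp").weighted_mean}
    if skull_mode is SkullMode.WHOLE:
        layers["whole_skull"] = recommended("whole_skull").weighted_mean
    else:
        layers["spongiform"] = recommended("spongiform").weighted_mean
        layers["inner_compact"] = recommended("inner_compact").weighted_mean
        layers["outer_compact"] = recommended("outer_compact").weighted_mean
    if include_csf:
        layers["csf"] = recommended("csf").weighted_mean
    if brain_mode is BrainMode.WHOLE:
        layers["whole_brain"] = recommended("whole_brain").weighted_mean
    else:
        layers["gm"] = recommended("gm").weighted_mean
        if wm_mode is WhiteMatterMode.ISOTROPIC:
            layers["wm"] = recommended("wm").weighted_mean
        else:
            layers["wm_par"] = recommended("wm_par").weighted_mean
            layers["wm_perp"] = recommended("wm_perp").weighted_mean
    return HeadProfile(
        layers=layers, skull_mode=skull_mode, brain_mode=brain_mode, wm_mode=wm_mode
    )


def sample_individual(
    tissue: TissueLabel | str,
    seed: int | np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw plausible individual conductivities for one tissue.

    Conductivities are strictly positive and right-skewed, so draws come
    from a log-normal matched to the entry's (weighted mean, SD) by moment
    matching, truncated by rejection to the observed [minimum, maximum].
    Entries without an SD (single-value tissues) return the weighted mean
    exactly.  Seeded and reproducible.
    """
    entry = recommended(tissue)
    scalar = size is None
    n = 1 if scalar else int(size)
    if entry.sd is None or entry.sd == 0:
        out = np.full(n, entry.weighted_mean)
        return float(out[0]) if scalar else out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, s = entry.weighted_mean, entry.sd
    log_var = math.log1p((s / m) ** 2)
    mu = math.log(m) - log_var / 2.0
    sigma = math.sqrt(log_var)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=mu, sigma=sigma, size=max(n - filled, 16))
        ok = draw[(draw >= entry.minimum) & (draw <= entry.maximum)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return float(out[0]) if scalar else out
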