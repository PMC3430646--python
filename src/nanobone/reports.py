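"""Tabular morphometry report shared by the phantom ground truth and the
segmentation-based measurement path."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _to_native(obj):
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class MorphometryReport:
    """Volumes, ratios and densities of the lacuno-canalicular network.

    ``lacunae`` has one row per lacuna (id, compartment, volume_um3, and a
    cross_cement_line flag where connectivity is known);
    ``per_compartment`` maps compartment name to summary statistics such as
    lacunar volume mean ± SD, canalicular-to-lacunar volume ratio (percent)
    and tissue density mean ± SD.
    """

    lacunae: pd.DataFrame
    per_compartment: dict = field(default_factory=dict)
    n_components: int | None = None
    n_cross_cement_components: int | None = None
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return _to_native(
            {
                "per_compartment": self.per_compartment,
                "n_components": self.n_components,
                "n_cross_cement_components": self.n_cross_cement_components,
                **self.extra,
            }
        )

    def to_json(self, path) -> None:
        payload = self.summary()
        payload["lacunae"] = _to_native(self.lacunae.to_dict(orient="records"))
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        self.lacunae.to_csv(path, index=False)
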