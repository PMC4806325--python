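"""The canonical 89-feature registry.

The registry is shipped as a versioned text table (name, class, dim, params)
and validated at load time: exactly 89 features in exactly 15 classes, with
17 features in the GLCM class.  Its row order is the canonical output and
heat-map order.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List

import numpy as np
import pandas as pd

REGISTRY_VERSION = "1.0"

N_FEATURES = 89
N_CLASSES = 15
N_GLCM = 17

#: Feature classes whose values derive from gray-level matrices; used by the
#: concordance summary of texture sensitivity to the reconstruction kernel.
MATRIX_TEXTURE_CLASSES = ("GLCM", "RunLength", "GTDM")


class RegistryError(RuntimeError):
    pass


@dataclass
class FeatureRegistry:
    """Ordered table of the 89 features in 15 classes."""

    table: pd.DataFrame
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = list(self.table["name"])
        if len(names) != len(set(names)):
            raise RegistryError("duplicate feature names in registry")
        if len(names) != N_FEATURES:
            raise RegistryError(f"registry must hold {N_FEATURES} features, found {len(names)}")
        classes = list(dict.fromkeys(self.table["class"]))
        if len(classes) != N_CLASSES:
            raise RegistryError(f"registry must hold {N_CLASSES} classes, found {len(classes)}")
        n_glcm = int((self.table["class"] == "GLCM").sum())
        if n_glcm != N_GLCM:
            raise RegistryError(f"GLCM class must hold {N_GLCM} features, found {n_glcm}")

    @property
    def names(self) -> List[str]:
        return list(self.table["name"])

    @property
    def classes(self) -> List[str]:
        return list(dict.fromkeys(self.table["class"]))

    def class_of(self, name: str) -> str:
        return self._class_map()[name]

    def _class_map(self) -> Dict[str, str]:
        return dict(zip(self.table["name"], self.table["class"]))

    def names_in_class(self, cls: str) -> List[str]:
        return list(self.table.loc[self.table["class"] == cls, "name"])

    def __len__(self) -> int:
        return len(self.table)


def load_registry() -> FeatureRegistry:
    """Load and validate the packaged registry table."""
    with resources.files("radiomics_repro.data").joinpath("feature_registry.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", dtype=str)
    table["params"] = table.get("params", pd.Series(dtype=str))
    return FeatureRegistry(table=table.reset_index(drop=True))


@dataclass
class FeatureVector:
    """The 89 named values for one (subject, scan, setting) extraction.

    Values are floats; a degenerate ROI yields NaN ("Not Available") with the
    reason recorded in ``na_reasons``.
    """

    registry: FeatureRegistry
    values: Dict[str, float]
    na_reasons: Dict[str, str]

    def __post_init__(self) -> None:
        missing = [n for n in self.registry.names if n not in self.values]
        if missing:
            raise RegistryError(f"feature vector missing {missing}")

    def to_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in self.registry.names}, dtype=float)

    def as_array(self) -> np.ndarray:
        return self.to_series().to_numpy()

    def __len__(self) -> int:
        return len(self.registry)
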