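"""The rectangular mixed-type dataset container and its CSV round trip.

Data are held in a :class:`pandas.DataFrame`: continuous columns as float64
(``NaN`` = missing), discrete columns as object arrays of level strings
(``NaN`` = missing).  A companion list of :class:`VariableSpec` carries the
typing information; on disk the pair is a plain CSV (missing cells written
as empty fields) plus a JSON variable-spec file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variables import VariableSpec, check_unique, load_specs, save_specs


@dataclass
class MixedDataset:
    frame: pd.DataFrame
    specs: list[VariableSpec]

    def __post_init__(self) -> None:
        check_unique(self.specs)
        names = [s.name for s in self.specs]
        if list(self.frame.columns) != names:
            missing = set(names) - set(self.frame.columns)
            if missing:
                raise ValueError(f"frame is missing declared columns: {sorted(missing)}")
            self.frame = self.frame[names]
        if len(self.frame) < 1:
            raise ValueError("dataset must contain at least one row")
        frame = self.frame.copy()
        for s in self.specs:
            col = frame[s.name]
            if s.is_continuous:
                frame[s.name] = pd.to_numeric(col, errors="raise").astype(float)
            else:
                vals = col.astype(object).where(col.notna(), np.nan)
                observed = {v for v in vals if isinstance(v, str)}
                bad = observed - set(s.levels)
                if bad:
                    raise ValueError(
                        f"column {s.name!r} contains undeclared levels {sorted(bad)}"
                    )
                frame[s.name] = vals
        self.frame = frame

    # -- basic facts ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def spec_of(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    def is_complete(self) -> bool:
        return not bool(self.frame.isna().to_numpy().any())

    def missing_fraction(self) -> float:
        return float(self.frame.isna().to_numpy().mean())

    def copy(self) -> "MixedDataset":
        return MixedDataset(self.frame.copy(), list(self.specs))

    def take_rows(self, index) -> "MixedDataset":
        return MixedDataset(self.frame.iloc[index].reset_index(drop=True), list(self.specs))

    # -- I/O ------------------------------------------------------------
    def to_csv(self, data_path: str | Path, spec_path: str | Path | None = None) -> None:
        self.frame.to_csv(data_path, index=False, na_rep="")
        if spec_path is not None:
            save_specs(self.specs, spec_path)

    @classmethod
    def from_csv(cls, data_path: str | Path, spec_path: str | Path) -> "MixedDataset":
        specs = load_specs(spec_path)
        dtypes = {s.name: (float if s.is_continuous else object) for s in specs}
        frame = pd.read_csv(data_path, dtype=dtypes, keep_default_na=True,
                            na_values=[""])
        return cls(frame, specs)
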