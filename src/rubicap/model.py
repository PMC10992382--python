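"""Model/Results front end for the two fitted quantities of the package.

``CaptureModel`` wraps the whole accounting pipeline for a set of strains:
construct it from rate tables (or a published-style DataFrame), call
``fit()`` to obtain a ``CaptureResults`` carrying flux partitions, carbon
and redox ledgers, Monte-Carlo uncertainties and a ``summary()`` table.

``MichaelisMenten`` wraps the carboxylation-kinetics fit the same way:
``MichaelisMenten(dataset).fit()`` returns a ``KineticsResults`` with
parameter estimates, standard errors and the derived catalytic efficiency.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .balances import monte_carlo_propagate, round_half_away, strain_summary
from .constants import NetworkConstants, StrainConfig, StrainRateTable
from .io import AnalysisConfig, run_capture_analysis, format_report
from .kinetics import (
    KineticDataset,
    KineticParams,
    catalytic_efficiency,
    fit_michaelis_menten,
    michaelis_menten,
)

__all__ = ["CaptureModel", "CaptureResults", "MichaelisMenten", "KineticsResults"]


class CaptureModel:
    """Carbon/redox accounting model for a set of capture strains.

    Parameters
    ----------
    tables : dict mapping strain id -> StrainRateTable
    constants : NetworkConstants, optional
    """

    def __init__(
        self,
        tables: dict[str, StrainRateTable],
        constants: Optional[NetworkConstants] = None,
    ) -> None:
        if not tables:
            raise ValueError("no strain tables supplied")
        self.tables = dict(tables)
        self.constants = constants or NetworkConstants()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        strain_configs: Optional[dict[str, StrainConfig]] = None,
        constants: Optional[NetworkConstants] = None,
    ) -> "CaptureModel":
        """Build from a species-rows × strain-columns DataFrame of
        ``value ± sd`` cells (the published table layout)."""
        import io as _io

        from .io import read_rate_table_csv

        buf = _io.StringIO()
        df.to_csv(buf)
        buf.seek(0)
        tables = read_rate_table_csv(buf, strain_configs, constants)
        return cls(tables, constants)

    def fit(
        self,
        propagate_uncertainty: bool = False,
        n_draws: int = 10_000,
        seed: int = 0,
    ) -> "CaptureResults":
        config = AnalysisConfig(
            constants=self.constants, mc_draws=n_draws, seed=seed
        )
        report = run_capture_analysis(
            self.tables, config, propagate_uncertainty=propagate_uncertainty
        )
        return CaptureResults(self, report)


class CaptureResults:
    """Fitted ledgers and comparisons for every strain of a CaptureModel."""

    def __init__(self, model: CaptureModel, report: dict) -> None:
        self.model = model
        self.report = report
        self.strains = report["strains"]
        self.comparisons = report["comparisons"]

    def per_strain(self, key: str) -> dict[str, float]:
        return {sid: entry[key] for sid, entry in self.strains.items()}

    def to_frame(self) -> pd.DataFrame:
        """Scalar results as a quantities × strains DataFrame."""
        keys = [k for k in next(iter(self.strains.values())) if k not in ("sd", "redox_feasible")]
        data = {sid: [entry[k] for k in keys] for sid, entry in self.strains.items()}
        return pd.DataFrame(data, index=keys)

    def summary(self) -> str:
        return format_report(self.report)


class MichaelisMenten:
    """Michaelis–Menten carboxylation model for one assay dataset."""

    def __init__(self, data: KineticDataset) -> None:
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MichaelisMenten":
        """Build from a DataFrame with ``co2_uM`` and ``rate_per_s`` columns
        (optionally ``replicate``)."""
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(
            KineticDataset(
                co2_concs=df["co2_uM"].to_numpy(dtype=float),
                rates=df["rate_per_s"].to_numpy(dtype=float),
                replicate=rep,
            )
        )

    def fit(self, init: Optional[tuple[float, float]] = None) -> "KineticsResults":
        params = fit_michaelis_menten(self.data, init=init)
        return KineticsResults(self, params)


class KineticsResults:
    """Fitted carboxylation parameters with uncertainties."""

    def __init__(self, model: MichaelisMenten, params: KineticParams) -> None:
        self.model = model
        self.kinetic_params = params
        self.params = {"kcat": params.kcat_c, "km": params.km_c}
        self.bse = {"kcat": params.kcat_c_sd, "km": params.km_c_sd}

    @property
    def efficiency(self) -> float:
        return self.kinetic_params.efficiency

    def predict(self, co2_concs) -> np.ndarray:
        return michaelis_menten(
            np.asarray(co2_concs, dtype=float),
            self.kinetic_params.kcat_c,
            self.kinetic_params.km_c,
        )

    def summary(self) -> str:
        p = self.kinetic_params
        lines = [
            "Michaelis-Menten carboxylation fit",
            f"  kcat_c  = {p.kcat_c:8.3f} ± {p.kcat_c_sd:.3f} s^-1",
            f"  K_M_c   = {p.km_c:8.2f} ± {p.km_c_sd:.2f} uM",
            f"  kcat/KM = {p.efficiency:8.2f} ± {p.efficiency_sd:.2f} s^-1 mM^-1",
            f"  n = {len(self.model.data.rates)} observations",
        ]
        return "\n".join(lines)
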