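"""Long-format trial datasets in NONMEM convention.

Columns: ID, TIME (h), AMT (ng; dose rows), DV (ng/mL; observation rows),
EVID (1 = dose, 0 = observation), MDV, SEX (0 = male, 1 = female),
WT (kg), BSA (m^2), plus optional covariate columns.  Each subject has
exactly one dose record at time 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SubjectCovariates

__all__ = ["SubjectRecord", "TrialDataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "SEX", "WT", "BSA"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's dose, observations and covariates, extracted for fitting."""

    subject_id: object
    dose_time: float
    dose_amount: float
    times: np.ndarray          # observation times (h)
    dv: np.ndarray             # observed concentrations (ng/mL)
    covariates: SubjectCovariates


@dataclass
class TrialDataset:
    df: pd.DataFrame
    lloq: float = 1.0
    _records: list[SubjectRecord] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        df = self.df
        if (df.loc[df.EVID == 0, "TIME"] < 0).any():
            raise ValueError("observation times must be >= 0")
        if (df.loc[df.EVID == 0, "DV"] < 0).any():
            raise ValueError("DV must be >= 0")
        for sid, grp in df.groupby("ID"):
            doses = grp[grp.EVID == 1]
            if len(doses) != 1 or doses.TIME.iloc[0] != 0:
                raise ValueError(
                    f"subject {sid!r} must have exactly one dose record at time 0"
                )

    @classmethod
    def from_csv(cls, path, lloq: float = 1.0) -> "TrialDataset":
        return cls(pd.read_csv(path), lloq=lloq)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    @property
    def n_subjects(self) -> int:
        return self.df.ID.nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df.EVID == 0).sum())

    def subjects(self) -> list[SubjectRecord]:
        """Per-subject records in subject-id order (cached)."""
        if self._records is None:
            records = []
            extra_cols = [c for c in self.df.columns if c not in REQUIRED_COLUMNS]
            for sid, grp in self.df.groupby("ID", sort=True):
                dose = grp[grp.EVID == 1].iloc[0]
                obs = grp[grp.EVID == 0].sort_values("TIME")
                cov = SubjectCovariates(
                    gender="female" if dose.SEX else "male",
                    bsa=float(dose.BSA),
                    body_weight=float(dose.WT),
                    biochemistry={c: float(dose[c]) for c in extra_cols
                                  if np.isfinite(pd.to_numeric(dose[c], errors="coerce"))},
                )
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        dose_time=float(dose.TIME),
                        dose_amount=float(dose.AMT),
                        times=obs.TIME.to_numpy(dtype=float),
                        dv=obs.DV.to_numpy(dtype=float),
                        covariates=cov,
                    )
                )
            self._records = records
        return self._records

    def resample_subjects(
        self, rng: np.random.Generator, stratify_on: str = "SEX"
    ) -> "TrialDataset":
        """Bootstrap resample of subjects with replacement, stratified.

        Stratification preserves each stratum's subject count (e.g. the
        gender split) in every replicate; resampled subjects get fresh ids.
        """
        per_subject = self.df.groupby("ID").first()
        frames, new_id = [], 1
        for _, ids in per_subject.groupby(stratify_on).groups.items():
            ids = list(ids)
            for pick in rng.choice(len(ids), size=len(ids), replace=True):
                block = self.df[self.df.ID == ids[pick]].copy()
                block["ID"] = new_id
                frames.append(block)
                new_id += 1
        return TrialDataset(pd.concat(frames, ignore_index=True), lloq=self.lloq)
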