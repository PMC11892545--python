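"""One-row-per-person longitudinal panel container and CSV plumbing.

Column convention (4-digit calendar-year suffixes):

* ``id`` -- person identifier;
* ``C_*`` -- baseline block (categoricals ``C_sex``, ``C_origin``,
  ``C_education``, ``C_region`` and numeric history summaries ``C_hist_*``);
* ``L_<name>_<year>`` -- pre-treatment time-varying covariates;
* ``X_<year>`` -- treatment, encoded ``NONE``/``SUPRA``/``SUB``;
* ``W_<name>_<year>`` -- post-treatment covariates;
* ``O_<year>`` -- under-observation flag (monotone non-increasing);
* ``Y_<year>`` -- event-by-year flag (monotone non-decreasing, defined from
  the second calendar year and only while observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .policies import LEVEL_NAMES, encode_levels, decode_levels


class PanelValidationError(ValueError):
    pass


class PanelParseError(ValueError):
    pass


@dataclass(frozen=True)
class PanelSchema:
    """Describes the block layout of a panel.

    ``n_treatment_years`` is the number of exposure years tau; observation
    flags span tau + 1 years and event flags the years 2..tau+1.
    """

    start_year: int
    n_treatment_years: int
    baseline_categorical: tuple[str, ...] = ()
    baseline_numeric: tuple[str, ...] = ()
    l_names: tuple[str, ...] = ()
    w_names: tuple[str, ...] = ()
    levels: tuple[str, ...] = LEVEL_NAMES
    has_censoring: bool = True

    @property
    def tau(self) -> int:
        return self.n_treatment_years

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.start_year + k for k in range(self.tau))

    def columns(self) -> list[str]:
        cols = ["id"]
        cols += list(self.baseline_categorical) + list(self.baseline_numeric)
        for year in self.years:
            cols += [f"L_{n}_{year}" for n in self.l_names]
            cols.append(f"X_{year}")
            cols += [f"W_{n}_{year}" for n in self.w_names]
        cols += [f"O_{self.start_year + k}" for k in range(self.tau + 1)]
        cols += [f"Y_{self.start_year + k}" for k in range(1, self.tau + 1)]
        return cols


def registry_schema(n_years: int = 11, start_year: int = 2011) -> PanelSchema:
    """Schema of the synthetic registry cohort."""
    return PanelSchema(
        start_year=start_year,
        n_treatment_years=n_years - 1,
        baseline_categorical=("C_sex", "C_origin", "C_education", "C_region"),
        baseline_numeric=(
            "C_hist_restorations",
            "C_hist_extractions",
            "C_hist_income_sum",
            "C_hist_years_supragingival",
            "C_hist_years_subgingival",
            "C_hist_years_perio_surgery",
            "C_hist_years_endodontic",
            "C_hist_years_radiograph",
            "C_hist_years_examination",
            "C_hist_years_prevention",
        ),
        l_names=("income", "diabetes"),
        w_names=("examination", "prevention", "radiograph", "endodontic", "restorations"),
    )


@dataclass
class PanelDataset:
    """A validated panel: a one-row-per-person DataFrame plus its schema."""

    df: pd.DataFrame
    schema: PanelSchema

    def __post_init__(self):
        self.validate()

    # -- basic accessors --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def tau(self) -> int:
        return self.schema.tau

    def treatment_matrix(self, codes: bool = True) -> np.ndarray:
        cols = [f"X_{y}" for y in self.schema.years]
        if self.n == 0:
            return np.zeros((0, self.tau), dtype=np.int8 if codes else object)
        mat = self.df[cols].to_numpy()
        return encode_levels(mat) if codes else mat.astype(object)

    def obs_matrix(self) -> np.ndarray:
        """(n, tau+1) observation flags; column t is year start_year + t."""
        cols = [f"O_{self.schema.start_year + k}" for k in range(self.tau + 1)]
        return self.df[cols].to_numpy(dtype=float).astype(bool) if self.n else np.zeros((0, self.tau + 1), bool)

    def event_matrix(self) -> np.ndarray:
        """(n, tau) event-by-year flags for years 2..tau+1; NaN while unobserved."""
        cols = [f"Y_{self.schema.start_year + k}" for k in range(1, self.tau + 1)]
        return self.df[cols].to_numpy(dtype=float) if self.n else np.zeros((0, self.tau))

    def set_treatments(self, matrix) -> "PanelDataset":
        """Return a copy with the X block replaced (e.g. a policy-shifted panel)."""
        out = self.df.copy()
        dec = decode_levels(encode_levels(matrix))
        for j, y in enumerate(self.schema.years):
            out[f"X_{y}"] = dec[:, j]
        return PanelDataset(out, self.schema)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in self.schema.columns() if c not in self.df.columns]
        if missing:
            raise PanelValidationError(f"missing columns: {missing}")
        if self.n == 0:
            return
        levels = set(self.schema.levels)
        for y in self.schema.years:
            bad = set(self.df[f"X_{y}"].astype(str)) - levels
            if bad:
                raise PanelValidationError(f"X_{y}: unknown treatment levels {sorted(bad)}")
        O = self.obs_matrix()
        if (np.diff(O.astype(int), axis=1) > 0).any():
            raise PanelValidationError("observation flags O must be monotone non-increasing")
        Y = self.event_matrix()
        with np.errstate(invalid="ignore"):
            inc = np.diff(Y, axis=1)
        if np.nanmin(inc, initial=0.0) < 0:
            bad_cols = [
                f"Y_{self.schema.start_year + 1 + j + 1}"
                for j in range(Y.shape[1] - 1)
                if np.nanmin(inc[:, j], initial=0.0) < 0
            ]
            raise PanelValidationError(
                f"event flags Y must be monotone non-decreasing (columns {bad_cols})"
            )
        # Y defined exactly where observed
        obs_y = O[:, 1:]
        defined = ~np.isnan(Y)
        if (defined & ~obs_y).any():
            raise PanelValidationError("event flags defined for unobserved person-years")
        if "diabetes" in self.schema.l_names:
            D = np.stack(
                [self.df[f"L_diabetes_{y}"].to_numpy(dtype=float) for y in self.schema.years],
                axis=1,
            )
            if (np.diff(D, axis=1) < 0).any():
                raise PanelValidationError("diabetes flag must be absorbing")

    # -- derived quantities ----------------------------------------------

    def event_ever(self) -> np.ndarray:
        """Event observed by each person's last observed year (bool, length n)."""
        Y = np.nan_to_num(self.event_matrix(), nan=0.0)
        return Y.max(axis=1, initial=0.0) > 0 if self.n else np.zeros(0, bool)

    def censored_by_end(self) -> np.ndarray:
        O = self.obs_matrix()
        return ~O[:, -1] if self.n else np.zeros(0, bool)


# -- summaries -------------------------------------------------------------


@dataclass
class CohortSummary:
    """Table-1-style marginals of a panel."""

    n_persons: int
    baseline_props: dict[str, float] = field(default_factory=dict)
    baseline_medians: dict[str, float] = field(default_factory=dict)
    yearly: pd.DataFrame | None = None
    censored_fraction: float = float("nan")
    cumulative_incidence: float = float("nan")
    treated_years_mean: float = float("nan")
    treated_years_sd: float = float("nan")
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_persons", self.n_persons)]
        rows += [(f"prop_{k}", v) for k, v in self.baseline_props.items()]
        rows += [(f"median_{k}", v) for k, v in self.baseline_medians.items()]
        rows += [
            ("censored_fraction", self.censored_fraction),
            ("cumulative_incidence", self.cumulative_incidence),
            ("treated_years_mean", self.treated_years_mean),
            ("treated_years_sd", self.treated_years_sd),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def summarize_cohort(panel: PanelDataset) -> CohortSummary:
    """Marginals over persons under observation in each year, loss to
    follow-up by end of window, cumulative event incidence as a share of the
    starting cohort, and mean/SD of per-person treated years."""
    panel.validate()
    n = panel.n
    if n == 0:
        return CohortSummary(n_persons=0, empty=True)
    df, schema = panel.df, panel.schema
    props: dict[str, float] = {}
    if "C_sex" in df:
        props["male"] = float((df["C_sex"] == "male").mean())
    if "C_origin" in df:
        props["danish_origin"] = float((df["C_origin"] == "danish").mean())
    if "C_education" in df:
        for lev, share in df["C_education"].value_counts(normalize=True).items():
            props[f"education_{lev}"] = float(share)
    if "C_region" in df:
        for lev, share in df["C_region"].value_counts(normalize=True).items():
            props[f"region_{lev}"] = float(share)
    medians = {
        c.removeprefix("C_"): float(df[c].median()) for c in schema.baseline_numeric
    }
    O = panel.obs_matrix()
    rows = []
    for j, year in enumerate(schema.years):
        obs = O[:, j]
        sub = df.loc[obs]
        row: dict[str, float] = {"year": year, "n_observed": int(obs.sum())}
        if "income" in schema.l_names:
            row["income_median"] = float(sub[f"L_income_{year}"].median())
        if "diabetes" in schema.l_names:
            row["diabetes_prev"] = float(sub[f"L_diabetes_{year}"].mean())
        for w in schema.w_names:
            col = f"W_{w}_{year}"
            row[f"{w}_rate"] = float(sub[col].mean())
        row["any_therapy_rate"] = float((sub[f"X_{year}"] != "NONE").mean())
        rows.append(row)
    from .policies import person_years_with_therapy

    counts, mean_ty, sd_ty = person_years_with_therapy(panel.treatment_matrix())
    return CohortSummary(
        n_persons=n,
        baseline_props=props,
        baseline_medians=medians,
        yearly=pd.DataFrame(rows),
        censored_fraction=float(panel.censored_by_end().mean()),
        cumulative_incidence=float(panel.event_ever().mean()),
        treated_years_mean=mean_ty,
        treated_years_sd=sd_ty,
    )


# -- CSV round trip --------------------------------------------------------


def write_panel(panel: PanelDataset, path) -> None:
    cols = panel.schema.columns()
    panel.df[cols].to_csv(path, index=False)


def infer_registry_schema(path) -> PanelSchema:
    """Recover the registry schema from a panel file's header (the treatment
    columns ``X_<year>`` determine the window)."""
    header = pd.read_csv(path, nrows=0).columns
    years = sorted(int(c.split("_")[1]) for c in header if c.startswith("X_"))
    if not years:
        raise PanelParseError("no treatment columns (X_<year>) in header")
    return registry_schema(n_years=len(years) + 1, start_year=years[0])


def read_panel(path, schema: PanelSchema) -> PanelDataset:
    df = pd.read_csv(path)
    missing = [c for c in schema.columns() if c not in df.columns]
    if missing:
        raise PanelParseError(f"missing columns: {missing}")
    for y in schema.years:
        df[f"X_{y}"] = df[f"X_{y}"].astype(str)
    return PanelDataset(df, schema)
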