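"""Read/write species × site matrices and study reports; bundled survey summary.

The package convention is rows = species, columns = sites.  Sites play the
role of resource states in the overlap analysis, so this orientation matches
the utilization-matrix indexing used throughout.  Values are non-negative
real abundances (session-averaged pitfall catches are real-valued, so
integer counts are not assumed anywhere).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .null_engine import NullModelResult

__all__ = [
    "AbundanceMatrix",
    "StudyDesign",
    "Table1Fixture",
    "MatrixValidationError",
    "MatrixParseError",
    "read_abundance_matrix",
    "write_matrix",
    "load_paper_fixture",
    "write_report",
    "read_null_result",
]


class MatrixValidationError(ValueError):
    """An input matrix violates a structural invariant (negative cell, duplicate id...)."""


class MatrixParseError(ValueError):
    """A delimited-text matrix could not be parsed (non-numeric cell, bad header...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class AbundanceMatrix:
    """Species × site abundance matrix, the raw input of every analysis.

    Parameters
    ----------
    species_ids
        Ordered unique species labels (rows).
    site_ids
        Ordered unique site labels (columns).
    values
        ``(n_species, n_sites)`` array of non-negative finite abundances,
        in units of mean individuals per trapping session.
    sector_of_site
        Optional mapping from site id to sector label.
    """

    species_ids: list[str]
    site_ids: list[str]
    values: np.ndarray
    sector_of_site: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.site_ids = [str(s) for s in self.site_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.species_ids), len(self.site_ids)):
            raise MatrixValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.species_ids)} species × {len(self.site_ids)} sites"
            )
        if len(self.species_ids) < 1 or len(self.site_ids) < 1:
            raise MatrixValidationError("need at least 1 species and 1 site")
        _check_unique(self.species_ids, "species")
        _check_unique(self.site_ids, "site")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite abundance for species {self.species_ids[i]!r} "
                f"at site {self.site_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise MatrixValidationError(
                f"negative abundance for species {self.species_ids[i]!r} "
                f"at site {self.site_ids[j]!r}: {self.values[i, j]}"
            )
        if self.sector_of_site is not None:
            missing = [s for s in self.site_ids if s not in self.sector_of_site]
            if missing:
                raise MatrixValidationError(
                    f"sector_of_site missing entries for sites {missing[:5]}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.site_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sector_of_site: Mapping[str, str] | None = None
    ) -> "AbundanceMatrix":
        return cls(
            species_ids=list(map(str, df.index)),
            site_ids=list(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
            sector_of_site=dict(sector_of_site) if sector_of_site else None,
        )

    def select_species(self, keep: Sequence[int]) -> "AbundanceMatrix":
        keep = list(keep)
        return AbundanceMatrix(
            species_ids=[self.species_ids[i] for i in keep],
            site_ids=list(self.site_ids),
            values=self.values[keep, :],
            sector_of_site=dict(self.sector_of_site) if self.sector_of_site else None,
        )


@dataclass(frozen=True)
class StudyDesign:
    """Pitfall-trap sampling design: sectors of sites, traps per site, sessions."""

    sectors: tuple[tuple[str, str, int], ...]  # (ecosystem, sector label, n_sites)
    traps_per_site: int = 5
    sessions: int = 5

    def __post_init__(self) -> None:
        if self.traps_per_site < 1 or self.sessions < 1:
            raise MatrixValidationError("traps_per_site and sessions must be positive")
        for eco, label, n in self.sectors:
            if n < 1:
                raise MatrixValidationError(f"sector {label!r} has non-positive n_sites")

    @property
    def n_sites(self) -> int:
        return sum(n for _, _, n in self.sectors)

    @property
    def total_samples(self) -> int:
        return sum(n * self.traps_per_site * self.sessions for _, _, n in self.sectors)

    def sites_in(self, sector: str) -> int:
        for _, label, n in self.sectors:
            if label == sector:
                return n
        raise KeyError(f"unknown sector {sector!r}")

    def ecosystem_of(self, sector: str) -> str:
        for eco, label, _ in self.sectors:
            if label == sector:
                return eco
        raise KeyError(f"unknown sector {sector!r}")


@dataclass(frozen=True)
class Table1Fixture:
    """Per-(species, sector) incidence and individual counts from the survey summary.

    ``table`` is a long-format frame with columns
    ``species, sector, n_sites, n_individuals``.
    """

    table: pd.DataFrame
    design: StudyDesign = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = self.table
        required = {"species", "sector", "n_sites", "n_individuals"}
        if not required.issubset(t.columns):
            raise MatrixValidationError(f"fixture table needs columns {sorted(required)}")
        bad = t[(t.n_sites == 0) != (t.n_individuals == 0)]
        if len(bad):
            raise MatrixValidationError(
                f"zero-incidence/zero-count mismatch for {bad.iloc[0].species!r}"
            )
        bad = t[(t.n_sites > 0) & (t.n_individuals < t.n_sites)]
        if len(bad):
            raise MatrixValidationError(
                f"fewer individuals than occupied sites for {bad.iloc[0].species!r}"
            )
        if self.design is not None:
            for _, row in t.iterrows():
                if row.n_sites > self.design.sites_in(row.sector):
                    raise MatrixValidationError(
                        f"{row.species!r} occupies more sites than sector {row.sector!r} has"
                    )

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species"]))

    @property
    def sectors(self) -> list[str]:
        return list(dict.fromkeys(self.table["sector"]))

    def counts(self, species: str, sector: str) -> tuple[int, int]:
        """(n_sites_occupied, n_individuals) for one species in one sector."""
        row = self.table[(self.table.species == species) & (self.table.sector == sector)]
        if len(row) != 1:
            raise KeyError(f"no fixture entry for ({species!r}, {sector!r})")
        return int(row.n_sites.iloc[0]), int(row.n_individuals.iloc[0])

    def sector_table(self, sector: str) -> pd.DataFrame:
        sub = self.table[self.table.sector == sector]
        if not len(sub):
            raise KeyError(f"unknown sector {sector!r}")
        return sub.set_index("species")[["n_sites", "n_individuals"]]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_abundance_matrix(
    path: str | Path, orientation: str = "rows-are-species"
) -> AbundanceMatrix:
    """Read a delimited species × site matrix.

    The delimiter (comma or tab) is auto-detected from the header line.
    ``orientation`` is ``"rows-are-species"`` (default) or ``"rows-are-sites"``;
    the latter transposes on read so the in-memory convention is always
    rows = species.
    """
    if orientation not in ("rows-are-species", "rows-are-sites"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    # locate non-numeric cells ourselves so the error can cite the line
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell {df.iat[i, j]!r} at line {i + 2} "
            f"(row {df.index[i]!r}, column {df.columns[j]!r}) of {path}"
        )
    if coerced.isna().to_numpy().any():
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise MatrixParseError(
            f"missing cell at line {i + 2} (row {df.index[i]!r}, "
            f"column {df.columns[j]!r}) of {path}; missing values are not allowed"
        )
    if orientation == "rows-are-sites":
        coerced = coerced.T
    return AbundanceMatrix.from_frame(coerced)


def write_matrix(m: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix as tab-delimited text (full float precision)."""
    df = m.to_frame()
    df.index.name = "species"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_paper_fixture() -> tuple[Table1Fixture, StudyDesign]:
    """Load the bundled survey summary: 25 carabid species × 6 steppe sectors.

    The design is 90 pitfall-trap sites — 15 in the desert steppe, 15 in each
    of three typical-steppe sectors and 15 in each of two meadow-steppe
    sectors — with 5 traps per site and 5 monthly sessions (2,250 samples).
    Only per-sector incidences and individual totals were published; the
    site-level matrices themselves were not, which is why the synthetic
    module exists.
    """
    design = StudyDesign(
        sectors=(
            ("desert", "desert", 15),
            ("typical", "typical_1", 15),
            ("typical", "typical_2", 15),
            ("typical", "typical_3", 15),
            ("meadow", "meadow_1", 15),
            ("meadow", "meadow_2", 15),
        ),
        traps_per_site=5,
        sessions=5,
    )
    with resources.files("nichenull.data").joinpath("table1.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return Table1Fixture(table=table, design=design), design


REPORT_COLUMNS = [
    "unit",
    "statistic",
    "algorithm",
    "observed_estimate",
    "observed_variance",
    "expected_estimate",
    "expected_variance",
    "p_lower",
    "p_upper",
    "iterations",
    "seed",
]


def _null_result_to_dict(r: "NullModelResult") -> dict:
    return {
        "label": r.label,
        "statistic": r.statistic_name,
        "algorithm": r.algorithm,
        "observed": r.observed,
        "observed_variance": r.observed_variance,
        "expected": r.expected,
        "expected_variance": r.expected_variance,
        "p_lower": r.p_lower,
        "p_upper": r.p_upper,
        "limits": {k: list(v) for k, v in r.limits.items()},
        "iterations": r.iterations,
        "seed": r.seed,
        "simulated": [float(x) for x in r.simulated],
    }


def write_report(results: Iterable["NullModelResult"], path: str | Path) -> list[Path]:
    """Write a TSV summary table plus one JSON null-distribution file per result.

    One row per result, in input order, with the observed and expected
    (null) estimate and variance, both tail probabilities, and the run
    metadata.  Returns the paths written (report first).
    """
    results = list(results)
    if not results:
        raise ValueError("write_report needs at least one result")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    written = [path]
    for i, r in enumerate(results):
        rows.append(
            {
                "unit": r.label,
                "statistic": r.statistic_name,
                "algorithm": r.algorithm,
                "observed_estimate": r.observed,
                "observed_variance": r.observed_variance,
                "expected_estimate": r.expected,
                "expected_variance": r.expected_variance,
                "p_lower": r.p_lower,
                "p_upper": r.p_upper,
                "iterations": r.iterations,
                "seed": r.seed,
            }
        )
        null_path = path.parent / f"null_{i:02d}_{r.label}_{r.statistic_name}_{r.algorithm}.json"
        with open(null_path, "w") as fh:
            json.dump(_null_result_to_dict(r), fh)
        written.append(null_path)
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
    return written


def read_null_result(path: str | Path) -> "NullModelResult":
    """Reload a serialized null distribution as a full NullModelResult."""
    from .null_engine import NullModelResult

    with open(path) as fh:
        d = json.load(fh)
    return NullModelResult(
        statistic_name=d["statistic"],
        label=d["label"],
        observed=d["observed"],
        observed_variance=d["observed_variance"],
        simulated=np.asarray(d["simulated"], dtype=float),
        expected=d["expected"],
        expected_variance=d["expected_variance"],
        p_lower=d["p_lower"],
        p_upper=d["p_upper"],
        limits={k: tuple(v) for k, v in d["limits"].items()},
        algorithm=d["algorithm"],
        iterations=d["iterations"],
        seed=d["seed"],
    )
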