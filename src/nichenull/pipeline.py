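"""End-to-end study workflow: pooled and per-sector null-model analyses.

A *study* runs, for every analysis unit (each pooled ecosystem matrix and
each sector matrix), the mean-Pianka overlap null under RA3 and RA2 and
the mean-C-score null under FF, then writes a report table (one row per
unit × statistic × algorithm), a serialized null distribution per run, a
histogram per run, and a hypothesis verdict per run:

* overlap runs: observed overlap significantly above the null → habitat
  patchiness forcing co-occurrence (H1); significantly below → species
  segregation (H2); otherwise the null H0 stands;
* C-score runs: significantly above → segregated; below → aggregated;
  otherwise random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix_io import (
    AbundanceMatrix,
    MatrixValidationError,
    read_abundance_matrix,
    write_report,
)
from .null_engine import NullModelResult, run_null
from .synthetic_data import SyntheticCommunitySpec, generate_community, generate_from_table1

__all__ = [
    "AnalysisConfig",
    "Verdict",
    "StudyResult",
    "pool_sectors",
    "verdict_for",
    "run_study",
    "survey_shaped_config",
]

log = logging.getLogger(__name__)

OVERLAP_OUTCOMES = ("H0-not-rejected", "H1-overlap-higher", "H2-overlap-lower")
CSCORE_OUTCOMES = ("random", "segregated", "aggregated")


@dataclass
class AnalysisConfig:
    """Resolved configuration of a full study.

    ``matrices`` maps sector labels to abundance matrices; ``pooling``
    maps ecosystem labels to the sector labels pooled into them.  Units
    are analyzed in order: pooled ecosystems first, then every sector.
    """

    matrices: dict[str, AbundanceMatrix]
    pooling: dict[str, list[str]] = field(default_factory=dict)
    overlap_algorithms: tuple[str, ...] = ("RA3", "RA2")
    iterations: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    output_dir: Path | None = None
    make_plots: bool = True
    p_value_method: str = "add-one"

    def __post_init__(self) -> None:
        if self.iterations < 100:
            raise ValueError("iterations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for eco, sectors in self.pooling.items():
            missing = [s for s in sectors if s not in self.matrices]
            if missing:
                raise ValueError(f"pooling for {eco!r} references unknown sectors {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Build a config from a YAML file.

        Each entry of ``matrices`` is one of ``{path: ...}``,
        ``{table1_sector: ...}`` or ``{synthetic: {...}}`` (keys of
        :class:`~nichenull.synthetic_data.SyntheticCommunitySpec`).
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        matrices: dict[str, AbundanceMatrix] = {}
        for label, src in raw.get("matrices", {}).items():
            if "path" in src:
                matrices[label] = read_abundance_matrix(
                    src["path"], src.get("orientation", "rows-are-species")
                )
            elif "table1_sector" in src:
                matrices[label] = generate_from_table1(
                    src["table1_sector"], seed=src.get("seed", raw.get("seed", 0))
                )
            elif "synthetic" in src:
                matrices[label] = generate_community(
                    SyntheticCommunitySpec(**src["synthetic"])
                )
            else:
                raise ValueError(f"matrix {label!r} needs path, table1_sector or synthetic")
        return cls(
            matrices=matrices,
            pooling={k: list(v) for k, v in raw.get("pooling", {}).items()},
            overlap_algorithms=tuple(raw.get("overlap_algorithms", ("RA3", "RA2"))),
            iterations=int(raw.get("iterations", 10_000)),
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw["output_dir"]) if "output_dir" in raw else None,
            make_plots=bool(raw.get("make_plots", True)),
            p_value_method=raw.get("p_value_method", "add-one"),
        )


@dataclass(frozen=True)
class Verdict:
    """Hypothesis outcome for one null-model run, derived purely from the
    stored tail probabilities and the significance level."""

    unit: str
    statistic: str
    algorithm: str
    outcome: str
    tail_p: float
    alpha: float


@dataclass
class StudyResult:
    results: list[NullModelResult]
    verdicts: list[Verdict]
    report_path: Path | None = None
    plot_paths: list[Path] = field(default_factory=list)
    skipped_units: list[str] = field(default_factory=list)


def pool_sectors(
    matrices: Mapping[str, AbundanceMatrix], pooling: Mapping[str, Sequence[str]]
) -> dict[str, AbundanceMatrix]:
    """Column-wise concatenation of sector matrices into ecosystem matrices.

    Species are aligned by id (union over sectors, zero-filled where a
    species is absent from a sector); site ids must not collide.
    """
    pooled: dict[str, AbundanceMatrix] = {}
    for eco, sector_labels in pooling.items():
        species: list[str] = []
        for s in sector_labels:
            for sp in matrices[s].species_ids:
                if sp not in species:
                    species.append(sp)
        site_ids: list[str] = []
        sector_of_site: dict[str, str] = {}
        blocks = []
        for s in sector_labels:
            m = matrices[s]
            dup = set(site_ids) & set(m.site_ids)
            if dup:
                raise MatrixValidationError(
                    f"duplicate site ids across sectors pooled into {eco!r}: {sorted(dup)[:5]}"
                )
            site_ids.extend(m.site_ids)
            for sid in m.site_ids:
                sector_of_site[sid] = (m.sector_of_site or {}).get(sid, s)
            block = np.zeros((len(species), m.n_sites))
            idx = {sp: i for i, sp in enumerate(m.species_ids)}
            for i, sp in enumerate(species):
                if sp in idx:
                    block[i, :] = m.values[idx[sp], :]
            blocks.append(block)
        pooled[eco] = AbundanceMatrix(
            species_ids=species,
            site_ids=site_ids,
            values=np.concatenate(blocks, axis=1),
            sector_of_site=sector_of_site,
        )
    return pooled


def verdict_for(result: NullModelResult, alpha: float = 0.05) -> Verdict:
    """Map a null-model result to its hypothesis outcome at level ``alpha``."""
    if result.statistic_name == "pianka-mean":
        if result.p_upper < alpha:
            outcome, p = "H1-overlap-higher", result.p_upper
        elif result.p_lower < alpha:
            outcome, p = "H2-overlap-lower", result.p_lower
        else:
            outcome, p = "H0-not-rejected", min(result.p_lower, result.p_upper)
    elif result.statistic_name == "cscore-mean":
        if result.p_upper < alpha:
            outcome, p = "segregated", result.p_upper
        elif result.p_lower < alpha:
            outcome, p = "aggregated", result.p_lower
        else:
            outcome, p = "random", min(result.p_lower, result.p_upper)
    else:
        raise ValueError(f"unknown statistic {result.statistic_name!r}")
    return Verdict(
        unit=result.label,
        statistic=result.statistic_name,
        algorithm=result.algorithm,
        outcome=outcome,
        tail_p=p,
        alpha=alpha,
    )


def _plot_histogram(result: NullModelResult, path: Path, alpha: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sim = result.simulated
    edges = np.histogram_bin_edges(sim, bins="fd") if np.ptp(sim) > 0 else 10
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(sim, bins=edges, color="steelblue", edgecolor="white")
    ax.axvline(result.observed, color="red", lw=1.8, label="observed")
    lo1, hi1 = result.limits["one_tailed"]
    lo2, hi2 = result.limits["two_tailed"]
    for x in (lo1, hi1):
        ax.axvline(x, color="black", ls=(0, (8, 4)), lw=1, label=None)
    for x in (lo2, hi2):
        ax.axvline(x, color="black", ls=(0, (2, 3)), lw=1, label=None)
    ax.set_xlabel(result.statistic_name)
    ax.set_ylabel("null frequency")
    ax.set_title(f"{result.label} — {result.algorithm}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


def _unit_order(config: AnalysisConfig) -> list[tuple[str, AbundanceMatrix]]:
    pooled = pool_sectors(config.matrices, config.pooling)
    units = list(pooled.items())
    units.extend(config.matrices.items())
    return units


def run_study(config: AnalysisConfig) -> StudyResult:
    """Run the full analysis plan over every unit of a study.

    Per unit: one overlap null per configured RA algorithm plus one FF
    C-score null, each with ``config.iterations`` simulations and a seed
    derived deterministically from the master seed.  Units with fewer
    than 2 usable species are skipped with a warning.  If
    ``config.output_dir`` is set, writes ``report.tsv``, one JSON null
    distribution and one histogram per run, and ``verdicts.tsv``.
    """
    units = _unit_order(config)
    statistics = [("pianka-mean", a) for a in config.overlap_algorithms]
    statistics.append(("cscore-mean", "FF"))
    master = np.random.SeedSequence(config.seed)
    run_seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(len(units) * len(statistics))]

    results: list[NullModelResult] = []
    skipped: list[str] = []
    k = 0
    for label, matrix in units:
        usable = int((matrix.values.sum(axis=1) > 0).sum())
        if usable < 2:
            log.warning("skipping unit %r: only %d species with occurrences", label, usable)
            skipped.append(label)
            k += len(statistics)
            continue
        for stat, alg in statistics:
            seed = run_seeds[k]
            k += 1
            log.info("unit=%s statistic=%s algorithm=%s iterations=%d seed=%d",
                     label, stat, alg, config.iterations, seed)
            results.append(
                run_null(
                    matrix,
                    statistic=stat,
                    algorithm=alg,
                    iterations=config.iterations,
                    seed=seed,
                    label=label,
                    p_value_method=config.p_value_method,
                )
            )
    verdicts = [verdict_for(r, config.alpha) for r in results]

    report_path = None
    plot_paths: list[Path] = []
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.tsv"
        write_report(results, report_path)
        pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(
            out / "verdicts.tsv", sep="\t", index=False
        )
        if config.make_plots:
            for i, r in enumerate(results):
                p = out / f"hist_{i:02d}_{r.label}_{r.statistic_name}_{r.algorithm}.png"
                _plot_histogram(r, p, config.alpha)
                plot_paths.append(p)
    return StudyResult(
        results=results,
        verdicts=verdicts,
        report_path=report_path,
        plot_paths=plot_paths,
        skipped_units=skipped,
    )


def survey_shaped_config(
    seed: int = 0,
    iterations: int = 10_000,
    output_dir: str | Path | None = None,
    make_plots: bool = True,
) -> AnalysisConfig:
    """Eight-unit study layout on surrogate sector matrices.

    Six sectors are generated from the bundled summary's marginals; the
    three typical-steppe sectors pool into one 45-site matrix and the two
    meadow-steppe sectors into one 30-site matrix, giving 8 analysis
    units (desert, typical, meadow, typical_1–3, meadow_1–2) and 24 runs.
    """
    ss = np.random.SeedSequence(seed)
    sector_labels = ["desert", "typical_1", "typical_2", "typical_3", "meadow_1", "meadow_2"]
    matrices = {
        lab: generate_from_table1(lab, seed=int(child.generate_state(1)[0] % 2**31))
        for lab, child in zip(sector_labels, ss.spawn(len(sector_labels)))
    }
    return AnalysisConfig(
        matrices=matrices,
        pooling={
            "typical": ["typical_1", "typical_2", "typical_3"],
            "meadow": ["meadow_1", "meadow_2"],
        },
        iterations=iterations,
        seed=seed,
        output_dir=Path(output_dir) if output_dir is not None else None,
        make_plots=make_plots,
    )
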