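"""On-disk formats: expression/label TSVs, signature lists, reports, configs.

Expression tables are TSV (or CSV) with gene identifiers in the first
column and one column per sample; labels are a two-column table
``sample`` / ``response`` with values 0/1.  Signatures are plain text,
one gene identifier per line, ``#`` comments and blank lines ignored.
Expression is assumed to be already variance-stabilized (log scale): the
reader validates finiteness and alignment but never re-normalizes, and
missing values are rejected rather than imputed.

All writers are deterministic: stable column order and fixed ``%.17g``
float formatting (which round-trips IEEE doubles exactly).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audit import AuditReport
from .cohorts import ExpressionCohort, GeneSignature, SigauditError
from .simulate import SimulationConfig

logger = logging.getLogger("sigaudit")

FLOAT_FORMAT = "%.17g"


def setup_logging(verbose: bool = False) -> None:
    """Structured logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("sigaudit")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class CohortTableSpec:
    """Where one cohort lives on disk and how its table is oriented."""

    expression_path: Path
    labels_path: Path
    name: str
    genes_in_rows: bool = True  # explicit flag; orientation is never sniffed

    def __post_init__(self) -> None:
        self.expression_path = Path(self.expression_path)
        self.labels_path = Path(self.labels_path)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort(spec: CohortTableSpec) -> ExpressionCohort:
    """Read and align one cohort from an expression table and a label table."""
    for p in (spec.expression_path, spec.labels_path):
        if not Path(p).exists():
            raise SigauditError(f"file not found: {p}")

    expr = pd.read_csv(
        spec.expression_path,
        sep=_sep_for(spec.expression_path),
        index_col=0,
        float_precision="round_trip",  # exact write -> read identity
    )
    if not spec.genes_in_rows:
        expr = expr.T
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise SigauditError(
            f"cohort {spec.name!r}: duplicate gene identifiers {dupes[:5]}"
        )
    try:
        values = expr.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SigauditError(
            f"cohort {spec.name!r}: non-numeric expression cells ({exc})"
        ) from exc
    if not np.isfinite(values).all():
        raise SigauditError(
            f"cohort {spec.name!r}: missing or non-finite expression values "
            "(imputation is not supported)"
        )

    lab = pd.read_csv(spec.labels_path, sep=_sep_for(spec.labels_path))
    required = {"sample", "response"}
    if not required.issubset(lab.columns):
        raise SigauditError(
            f"labels file {spec.labels_path} must have columns {sorted(required)}"
        )
    lab = lab.set_index(lab["sample"].astype(str))
    samples = [str(s) for s in expr.columns]
    missing = [s for s in samples if s not in lab.index]
    if missing:
        raise SigauditError(
            f"cohort {spec.name!r}: samples present in expression but absent "
            f"from labels: {missing}"
        )
    response = lab.loc[samples, "response"]
    if not response.isin([0, 1]).all():
        bad = sorted(set(response[~response.isin([0, 1])]))
        raise SigauditError(
            f"cohort {spec.name!r}: label values outside {{0, 1}}: {bad[:5]}"
        )
    return ExpressionCohort(
        name=spec.name,
        genes=[str(g) for g in expr.index],
        samples=samples,
        values=values,
        labels=response.to_numpy(dtype=int),
        metadata={"expression_path": str(spec.expression_path)},
    )


def write_cohort(cohort: ExpressionCohort, out_dir: Path) -> CohortTableSpec:
    """Write one cohort as ``<name>.expression.tsv`` + ``<name>.labels.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr_path = out_dir / f"{cohort.name}.expression.tsv"
    labels_path = out_dir / f"{cohort.name}.labels.tsv"
    cohort.to_frame().to_csv(
        expr_path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene"
    )
    pd.DataFrame({"sample": cohort.samples, "response": cohort.labels}).to_csv(
        labels_path, sep="\t", index=False
    )
    return CohortTableSpec(expr_path, labels_path, cohort.name)


def read_signature(path: Path, name: str | None = None) -> GeneSignature:
    """Read a signature: one identifier per line, ``#`` comments ignored."""
    path = Path(path)
    genes: list[str] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise SigauditError(f"signature file {path} contains no gene identifiers")
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise SigauditError(f"signature file {path}: duplicated identifier {g!r}")
        seen.add(g)
    return GeneSignature(name or path.stem, genes)


def write_signature(signature: GeneSignature, path: Path) -> None:
    Path(path).write_text("\n".join(signature.genes) + "\n")


def load_simulation_config(path: Path) -> SimulationConfig:
    """Read a YAML file whose keys mirror :class:`SimulationConfig`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SigauditError(f"config {path} is not a YAML mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise SigauditError(f"config {path}: unknown fields {sorted(unknown)}")
    return SimulationConfig(**doc)


def dump_simulation_config(config: SimulationConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_report(report: AuditReport, out_dir: Path) -> dict[str, Path]:
    """Write an audit report as two tidy CSVs plus a JSON summary.

    Returns the paths written.  Output is byte-deterministic for
    identical reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "random_null_csv": out_dir / "random_signature_null.csv",
        "cross_cohort_csv": out_dir / "cross_cohort_auc.csv",
        "report_json": out_dir / "report.json",
    }
    report.null_frame().to_csv(
        paths["random_null_csv"], index=False, float_format=FLOAT_FORMAT
    )
    report.cross_frame().to_csv(
        paths["cross_cohort_csv"], index=False, float_format=FLOAT_FORMAT
    )
    paths["report_json"].write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    logger.info("report written to %s", out_dir)
    return paths
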