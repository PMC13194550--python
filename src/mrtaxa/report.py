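"""Forest-table serialization and run manifests.

The forest table is the package's tab-delimited, diff-able results format:
one row per (exposure, cohort, method) with the estimate, 95% CI, p-value,
instrument count and heterogeneity columns, on either the log-odds (beta) or
odds-ratio scale.  Floats are rendered with 6 significant digits in UTF-8
with a fixed column order.

A :class:`RunManifest` records everything needed to reproduce a CLI run
byte-identically: the full config echo, every seed, SHA-256 digests of input
files, the package version and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError
from .estimators import MREstimate
from .pipeline import MetaResult, ScreenResult, to_odds_ratio

FOREST_COLUMNS = [
    "exposure", "direction", "cohort", "method", "estimate", "ci_low", "ci_high",
    "se", "pval", "n_snp", "q_stat", "q_pval", "tau2", "status",
]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, str):
        return x
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


def _estimate_rows(label: str, direction: str, cohort: str,
                   estimates: dict[str, MREstimate], scale: str,
                   ci_level: float, status: str):
    z_rows = []
    for method, e in estimates.items():
        or_, lo, hi = to_odds_ratio(e, ci_level)
        if scale == "or":
            est, ci_l, ci_h = or_, lo, hi
        else:
            from scipy.stats import norm
            z = norm.ppf(0.5 + ci_level / 2)
            est, ci_l, ci_h = e.beta, e.beta - z * e.se, e.beta + z * e.se
        z_rows.append({
            "exposure": label, "direction": direction, "cohort": cohort,
            "method": method, "estimate": est, "ci_low": ci_l, "ci_high": ci_h,
            "se": e.se, "pval": e.pval, "n_snp": e.n_snp,
            "q_stat": e.q_stat, "q_pval": e.q_pval, "tau2": e.tau2,
            "status": status,
        })
    return z_rows


def render_forest_table(results: list[ScreenResult], scale: str = "or",
                        ci_level: float = 0.95) -> str:
    """Render screen results as a tab-delimited forest table string."""
    if not results:
        raise InputError("no results to render")
    if scale not in ("beta", "or"):
        raise InputError(f"scale must be 'beta' or 'or', got {scale!r}")
    rows = []
    for r in results:
        if r.status != "ok" and not r.estimates:
            rows.append({c: None for c in FOREST_COLUMNS}
                        | {"exposure": r.exposure_label, "direction": r.direction,
                           "cohort": r.cohort, "method": "none", "status": r.status})
            continue
        rows += _estimate_rows(r.exposure_label, r.direction, "discovery",
                               r.estimates, scale, ci_level, r.status)
        if r.replication_estimates:
            rows += _estimate_rows(r.exposure_label, r.direction, "replication",
                                   r.replication_estimates, scale, ci_level,
                                   "replicated" if r.replicated else "not_replicated")
        for meta, tag in ((r.meta, "meta"), (r.meta_dl_result, "meta_dl")):
            if meta is None:
                continue
            e = MREstimate(method=f"{tag}_{meta.model}", beta=meta.beta_meta,
                           se=meta.se_meta, pval=meta.pval_meta,
                           n_snp=len(meta.cohort_betas),
                           q_stat=meta.cochran_q_between,
                           q_pval=meta.q_pval_between)
            rows += _estimate_rows(r.exposure_label, r.direction, "meta",
                                   {e.method: e}, scale, ci_level, r.status)
    lines = ["\t".join(FOREST_COLUMNS)]
    for row in rows:
        lines.append("\t".join(_fmt(row.get(c)) for c in FOREST_COLUMNS))
    return "\n".join(lines) + "\n"


def parse_forest_table(text: str) -> pd.DataFrame:
    """Parse a rendered forest table back into a DataFrame."""
    return pd.read_csv(StringIO(text), sep="\t", na_values=["NA"])


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    row_counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command, "config": self.config, "seed": self.seed,
            "inputs": self.inputs, "row_counts": self.row_counts,
            "version": self.version, "python": self.python,
            "timestamp": self.timestamp,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(command=d["command"], config=d["config"], seed=d["seed"],
                   inputs=d.get("inputs", {}), row_counts=d.get("row_counts", {}),
                   version=d.get("version", __version__),
                   python=d.get("python", ""), timestamp=d.get("timestamp", ""))
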