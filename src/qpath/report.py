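"""Approach comparison reports.

For each named surgical approach this module scores the clinician's
hand-drawn corridor (total risk over its voxels), runs the Q-learning
planner from the approach's entry point, and tabulates the planner path's
Q-score and risk sum (Qr). Approaches are ranked ascending by Q-score —
the lowest-Q corridor is the recommended one. Every report embeds the
planner configuration hash, the seed and a checksum of the risk volume so a
reported ranking can be re-derived exactly.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import QPathError
from .geometry import PathwayMask, path_total_risk
from .planner import QLearningConfig, plan
from .volume import RiskVolume

_COLUMNS = ["name", "hand_total_risk", "q_score", "qr_score", "rank_by_q", "status"]


@dataclass
class ApproachCase:
    """One named approach: its hand-drawn corridor and planner endpoints."""

    name: str
    hand_mask: PathwayMask | set
    entry: tuple[int, int, int]
    target: frozenset

    def __post_init__(self):
        self.entry = tuple(int(c) for c in self.entry)
        self.target = frozenset(tuple(int(c) for c in t) for t in self.target)
        if not self.target:
            raise QPathError(f"approach {self.name!r} has an empty target")


@dataclass
class ApproachReport:
    """Rows of (name, hand risk, Q, Qr, rank) plus run provenance."""

    rows: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=_COLUMNS)

    @property
    def any_failed(self) -> bool:
        return any(r["status"] != "ok" for r in self.rows)


def _config_hash(config: QLearningConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _volume_checksum(risk: RiskVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(risk.risk).tobytes())
    h.update(np.asarray(risk.spacing_mm, dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


def compare_approaches(cases: list[ApproachCase], risk: RiskVolume,
                       config: QLearningConfig) -> ApproachReport:
    """Score every approach and rank by ascending Q-score.

    Each case is independent: its hand corridor is summed over the risk
    field, and the planner is run from its entry to its target. A planner
    failure marks the row ``failed`` (scores NaN, unranked) but the
    comparison continues. Ties on Q-score break by name.
    """
    if not cases:
        raise QPathError("need at least one approach case")
    names = [c.name for c in cases]
    if len(set(names)) != len(names):
        raise QPathError("approach names must be unique")
    rows = []
    for case in cases:
        row = {"name": case.name, "status": "ok"}
        row["hand_total_risk"] = path_total_risk(case.hand_mask, risk)
        try:
            result = plan(risk, case.entry, case.target, config)
            row["q_score"] = result.q_score
            row["qr_score"] = result.qr_score
        except QPathError as exc:
            row["q_score"] = float("nan")
            row["qr_score"] = float("nan")
            row["status"] = f"failed: {exc}"
        rows.append(row)
    ranked = sorted(
        (r for r in rows if r["status"] == "ok"),
        key=lambda r: (r["q_score"], r["name"]),
    )
    for rank, row in enumerate(ranked, start=1):
        row["rank_by_q"] = rank
    for row in rows:
        row.setdefault("rank_by_q", None)
    provenance = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "risk_volume_checksum": _volume_checksum(risk),
        "n_cases": len(cases),
    }
    return ApproachReport(rows=rows, provenance=provenance)


def render_report(report: ApproachReport, format: str = "markdown") -> str:
    """Serialise a report as csv, json or a markdown comparison table."""
    df = report.to_frame()
    if format == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "json":
        return json.dumps(
            {"rows": report.rows, "provenance": report.provenance},
            indent=2, sort_keys=True, allow_nan=True,
        )
    if format == "markdown":
        lines = [
            "| Pathway | Total risk score | Total Q-value | Qr | Rank |",
            "| --- | --- | --- | --- | --- |",
        ]
        for r in report.rows:
            rank = r["rank_by_q"] if r["rank_by_q"] is not None else r["status"]
            lines.append(
                f"| {r['name']} | {r['hand_total_risk']:.4g} "
                f"| {r['q_score']:.4g} | {r['qr_score']:.4g} | {rank} |"
            )
        lines.append("")
        prov = report.provenance
        lines.append(
            f"config `{prov.get('config_hash', '')}` · seed {prov.get('seed', '')} "
            f"· volume `{prov.get('risk_volume_checksum', '')}`"
        )
        return "\n".join(lines) + "\n"
    raise QPathError(f"unknown report format {format!r} (csv, json, markdown)")
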