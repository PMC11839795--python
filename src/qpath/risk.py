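"""Segment risk tables and per-voxel risk assignment.

A risk table maps anatomical segment names to penalty scores in [0, 1]
(0 = risk-free, 1 = penalised structure), the way a clinical team would rate
a parcellation. :func:`assign_risk` paints those scores onto a labelled
volume; :func:`fuse_layers` combines risk fields from several modalities
(parcellation, angiography vessels, tractography bundles) into one cost
field.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FusionError, MissingScoreError, RiskTableError
from .volume import LabeledVolume, RiskVolume


def normalize_segment_name(name: str) -> str:
    """Canonical form used for matching: stripped, internal whitespace
    collapsed, case-folded."""
    return " ".join(str(name).split()).casefold()


@dataclass
class RiskTable:
    """Segment-name -> penalty score in [0, 1].

    Lookup is whitespace- and case-insensitive; the original spellings are
    retained for display.
    """

    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        canonical: dict[str, float] = {}
        display: dict[str, str] = {}
        for name, score in self.scores.items():
            key = normalize_segment_name(name)
            score = float(score)
            if not 0.0 <= score <= 1.0:
                raise RiskTableError(
                    f"risk score for {name!r} is {score:g}, outside [0, 1]"
                )
            if key in canonical and canonical[key] != score:
                raise RiskTableError(
                    f"segment {display[key]!r} listed twice with conflicting "
                    f"scores {canonical[key]:g} and {score:g}"
                )
            canonical[key] = score
            display.setdefault(key, " ".join(str(name).split()))
        self._canonical = canonical
        self.scores = {display[k]: v for k, v in canonical.items()}

    def __len__(self) -> int:
        return len(self._canonical)

    def __contains__(self, name: str) -> bool:
        return normalize_segment_name(name) in self._canonical

    def score(self, name: str) -> float:
        key = normalize_segment_name(name)
        if key not in self._canonical:
            raise MissingScoreError([name])
        return self._canonical[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment_name": list(self.scores), "risk_score": list(self.scores.values())}
        )


def load_risk_table(source) -> RiskTable:
    """Parse a two-column CSV/TSV of ``segment_name, risk_score`` rows.

    ``source`` is a path, file object, or literal table text. A header row is
    accepted but not required. Duplicate names with the same score collapse
    silently; duplicates with conflicting scores raise
    :class:`~qpath.errors.RiskTableError` naming the segment.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if ("\n" in s) or ("," in s and not s.strip().endswith((".csv", ".tsv"))):
            text = s
        else:
            with open(s, "r", encoding="utf-8") as fh:
                text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, comment="#",
                     skip_blank_lines=True, dtype=str)
    if df.shape[1] != 2:
        raise RiskTableError(f"expected 2 columns, got {df.shape[1]}")
    first = str(df.iloc[0, 1]).strip()
    try:
        float(first)
    except ValueError:  # header row
        df = df.iloc[1:]
    if df.empty:
        return RiskTable({})
    scores: dict[str, float] = {}
    seen: dict[str, float] = {}
    for name, raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        try:
            score = float(str(raw).strip())
        except ValueError:
            raise RiskTableError(f"non-numeric risk score {raw!r} for {name!r}")
        key = normalize_segment_name(name)
        if key in seen and seen[key] != score:
            raise RiskTableError(
                f"segment {name!r} listed twice with conflicting scores "
                f"{seen[key]:g} and {score:g}"
            )
        seen[key] = score
        scores[str(name).strip()] = score
    return RiskTable(scores)


def assign_risk(volume: LabeledVolume, table: RiskTable,
                default: float | None = None) -> RiskVolume:
    """Map every voxel's label to its segment's risk score.

    Labels whose segment name is missing from the table fall back to
    ``default`` when given; without a default, unmapped names raise
    :class:`~qpath.errors.MissingScoreError` listing them all — unscored
    anatomy fails loudly rather than silently scoring 0.
    """
    labels_present = volume.present_labels()
    missing_names = []
    lut_pairs = {}
    for lab in labels_present:
        lab = int(lab)
        name = volume.names.get(lab)
        if name is not None and name in table:
            lut_pairs[lab] = table.score(name)
        elif default is not None:
            lut_pairs[lab] = float(default)
        else:
            missing_names.append(name if name is not None else f"<label {lab}>")
    if missing_names:
        raise MissingScoreError(missing_names)
    max_label = int(labels_present.max(initial=0))
    lut = np.zeros(max_label + 1, dtype=np.float64)
    for lab, sc in lut_pairs.items():
        lut[lab] = sc
    return RiskVolume(lut[volume.labels], volume.spacing_mm, volume.origin_mm)


def fuse_layers(layers: list[RiskVolume], mode: str = "max") -> RiskVolume:
    """Combine multi-modality risk fields voxelwise.

    mode="max" keeps the highest penalty at each voxel (the default: where
    aligned modalities disagree, the most dangerous rating wins);
    mode="sum_clipped" adds the layers and clips at 1 so the result stays a
    valid penalty field.
    """
    if not layers:
        raise FusionError("need at least one layer")
    ref = layers[0]
    for lay in layers[1:]:
        if lay.risk.shape != ref.risk.shape:
            raise FusionError(
                f"shape mismatch: {lay.risk.shape} vs {ref.risk.shape}"
            )
        if not np.allclose(lay.spacing_mm, ref.spacing_mm):
            raise FusionError(
                f"spacing mismatch: {lay.spacing_mm} vs {ref.spacing_mm}"
            )
    stack = np.stack([lay.risk for lay in layers])
    if mode == "max":
        fused = stack.max(axis=0)
    elif mode == "sum_clipped":
        fused = np.clip(stack.sum(axis=0), 0.0, 1.0)
    else:
        raise FusionError(f"unknown fusion mode {mode!r} (use 'max' or 'sum_clipped')")
    return RiskVolume(fused, ref.spacing_mm, ref.origin_mm)
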