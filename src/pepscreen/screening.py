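"""Candidate funnel: released ∩ observed peptides → QSAR prediction → threshold.

Reproduces the screening chain used to nominate ACE-inhibitory peptide
candidates from a protein hydrolysate: the peptides released by in silico
hydrolysis are intersected with the experimentally observed (MS-identified)
peptide list, restricted to lengths that have a trained QSAR model, predicted,
and selected below an IC50 threshold.

Every stage shrinks (or preserves) its input, so candidate counts are
monotone down the funnel; identical inputs and configuration give
byte-identical reports.

The packaged fixture ``data/predicted_ic50.csv`` carries the 21 screened
(peptide, predicted IC50) pairs of the source study, used by the tests to pin
the funnel's selection counts (6 below 10 µM, 16 below 100 µM).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .proteolysis import Peptide
from .qsar import PlsModel, PredictionRecord, predict_many

TABLE_FIXTURE = Path(__file__).parent / "data" / "predicted_ic50.csv"
DEFAULT_LENGTHS = frozenset({3, 6, 7, 8})

REPORT_COLUMNS = [
    "peptide", "length", "predicted_ic50_uM", "selected",
    "parent_id", "start", "end",
]


def _il_collapse(seq: str) -> str:
    return seq.replace("I", "L")


def match_peptides(released: Sequence[Peptide], observed: Sequence[str],
                   *, il_equivalent: bool = False) -> list[Peptide]:
    """Exact-sequence intersection of released fragments with an observed list.

    I and L are distinct by default (their z-scales differ, so predictions
    differ); ``il_equivalent=True`` collapses them, because mass spectrometry
    cannot tell the isobaric pair apart.  Duplicate released fragments with
    the same sequence collapse to their first occurrence (N→C order), keeping
    its parent coordinates as provenance.
    """
    if not released or not observed:
        raise ValueError("both the released and the observed list must be non-empty")
    key = _il_collapse if il_equivalent else (lambda s: s)
    observed_keys = {key(s) for s in observed}
    matched: dict[str, Peptide] = {}
    for pep in released:
        k = key(pep.sequence)
        if k in observed_keys and k not in matched:
            matched[k] = pep
    return list(matched.values())


def filter_by_length(peptides: Sequence[Peptide],
                     allowed: frozenset[int] = DEFAULT_LENGTHS) -> list[Peptide]:
    """Keep peptides whose length has a trained QSAR model; order preserved."""
    return [p for p in peptides if len(p) in allowed]


def filter_by_mass(peptides: Sequence[Peptide],
                   max_da: float = 3000.0) -> list[Peptide]:
    """Optional monoisotopic-mass gate (proxy for <3 kDa ultrafiltration)."""
    return [
        p for p in peptides
        if molecular_weight(p.sequence, seq_type="protein", monoisotopic=True) < max_da
    ]


@dataclass(frozen=True)
class ScreeningReport:
    """Ranked candidate table with the thresholds and per-length counts used."""

    table: pd.DataFrame
    threshold_uM: float
    report_thresholds_uM: tuple[float, ...]
    counts_below: dict[float, int]
    counts_per_length: dict[int, int]

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold_uM": self.threshold_uM,
            "counts_below": {f"{t:g}": c for t, c in self.counts_below.items()},
            "counts_per_length": {str(k): v for k, v in
                                  sorted(self.counts_per_length.items())},
            "n_candidates": int(len(self.table)),
            "n_selected": int(self.table["selected"].sum()),
            "selected_peptides": self.selected["peptide"].tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def select_candidates(predictions: Sequence[PredictionRecord],
                      threshold_uM: float = 10.0,
                      *,
                      report_thresholds_uM: Sequence[float] = (10.0, 100.0),
                      provenance: Mapping[str, Peptide] | None = None
                      ) -> ScreeningReport:
    """Rank predictions by IC50 and flag candidates under the threshold.

    The report is sorted ascending by predicted IC50 (ties broken by peptide
    sequence for determinism) and carries candidate counts under each
    configured reporting threshold.
    """
    if not predictions:
        raise ValueError("no predictions to screen")
    if threshold_uM <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    for rec in predictions:
        prov = provenance.get(rec.peptide) if provenance else None
        rows.append({
            "peptide": rec.peptide,
            "length": len(rec.peptide),
            "predicted_ic50_uM": rec.predicted_ic50,
            "selected": rec.predicted_ic50 < threshold_uM,
            "parent_id": prov.parent_id if prov else "",
            "start": prov.start if prov else pd.NA,
            "end": prov.end if prov else pd.NA,
        })
    table = (pd.DataFrame(rows, columns=REPORT_COLUMNS)
             .sort_values(["predicted_ic50_uM", "peptide"], kind="mergesort")
             .reset_index(drop=True))
    counts_below = {
        float(t): int((table["predicted_ic50_uM"] < t).sum())
        for t in report_thresholds_uM
    }
    counts_per_length = (
        table.groupby("length").size().astype(int).to_dict()
    )
    return ScreeningReport(
        table=table,
        threshold_uM=float(threshold_uM),
        report_thresholds_uM=tuple(float(t) for t in report_thresholds_uM),
        counts_below=counts_below,
        counts_per_length=counts_per_length,
    )


def load_prediction_fixture(path: str | Path = TABLE_FIXTURE
                            ) -> list[PredictionRecord]:
    """The packaged 21-peptide (sequence, predicted IC50 µM) fixture."""
    import numpy as np
    df = pd.read_csv(path, comment="#")
    return [
        PredictionRecord(
            peptide=row.peptide,
            predicted_log_ic50=float(np.log10(row.predicted_ic50_uM)),
            predicted_ic50=float(row.predicted_ic50_uM),
            model_length_class=len(row.peptide),
        )
        for row in df.itertuples()
    ]


def screen(released: Sequence[Peptide], observed: Sequence[str],
           models: dict[int, PlsModel], threshold_uM: float = 10.0,
           *, il_equivalent: bool = False,
           max_mass_da: float | None = None) -> ScreeningReport:
    """Run the full funnel: match → length filter → predict → select."""
    matched = match_peptides(released, observed, il_equivalent=il_equivalent)
    if max_mass_da is not None:
        matched = filter_by_mass(matched, max_mass_da)
    kept = filter_by_length(matched, frozenset(models))
    predictions = predict_many(models, [p.sequence for p in kept])
    provenance = {p.sequence: p for p in kept}
    return select_candidates(predictions, threshold_uM, provenance=provenance)
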