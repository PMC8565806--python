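"""One-command orchestration: ingest/simulate -> preprocess -> describe ->
signal mining -> off-label flags -> (for simulated data) recovery scoring.

The run is driven by a flat YAML/dict config and leaves behind a
:class:`RunManifest` recording input hashes, the config snapshot, per-stage
row counts and timestamps.  Manifest equality ignores timestamps, so two runs
of the same config and seed compare equal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd

from . import __version__
from .data_model import (
    Causality,
    load_dictionary,
    load_drug_labels,
    read_reports,
    write_reports,
    DrugDictionary,
    ADRDictionary,
)
from .descriptive import (
    adr_frequency,
    outcome_summary,
    route_summary,
    severity_by_stratum,
    severity_summary,
    sex_summary,
)
from .disproportionality import mine_signals, off_label_flags, signals_to_frame
from .preprocess import InclusionCriteria, expand_events, filter_reports, normalize_reports
from .synthetic import Implant, default_config, evaluate_recovery, generate_reports


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunManifest:
    input_hashes: dict[str, str]
    config: dict[str, Any]
    version: str
    counts: dict[str, int]
    started: str = ""
    finished: str = ""

    def __eq__(self, other: object) -> bool:  # timestamps excluded by design
        if not isinstance(other, RunManifest):
            return NotImplemented
        return (
            self.input_hashes == other.input_hashes
            and self.config == other.config
            and self.version == other.version
            and self.counts == other.counts
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _criteria_from_config(cfg: dict[str, Any]) -> InclusionCriteria:
    crit = cfg.get("criteria", {}) or {}
    allowed = crit.get("causality", ["certain", "probable", "possible"])
    return InclusionCriteria(
        age_min=int(crit.get("age_min", 0)),
        age_max=int(crit.get("age_max", 14)),
        causality_allowed=frozenset(Causality(c) for c in allowed),
    )


def run_pipeline(config: dict[str, Any], out_dir: Union[str, Path]) -> RunManifest:
    """Execute every stage and write the outputs plus ``manifest.json``.

    ``config`` either names a ``reports`` CSV or contains a ``simulate`` block
    (``n_reports``, optional ``implants`` triples, the ``seed`` applies);
    optional ``drug_dict`` / ``adr_dict`` / ``labels`` paths switch on
    normalization and off-label flagging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = dt.datetime.now(dt.timezone.utc).isoformat()
    input_hashes: dict[str, str] = {}
    counts: dict[str, int] = {}
    seed = int(config.get("seed", 0))

    @_stage("input")
    def load_input():
        if "simulate" in config:
            sim = dict(config["simulate"] or {})
            implants = tuple(
                Implant(str(d), str(a), float(r)) for d, a, r in sim.pop("implants", [])
            )
            sim.setdefault("n_reports", 15_857)
            sim["n_reports"] = int(sim["n_reports"])
            cfg = default_config(seed=seed, implants=implants, **sim)
            return generate_reports(cfg), cfg
        if "reports" in config:
            path = Path(config["reports"])
            input_hashes["reports"] = _sha256(path)
            return read_reports(path).reports, None
        raise ValueError("config needs a 'reports' path or a 'simulate' block")

    reports, sim_cfg = load_input()
    counts["reports_in"] = len(reports)

    @_stage("normalize")
    def normalize(reports):
        drug_dict: Optional[DrugDictionary] = None
        adr_dict: Optional[ADRDictionary] = None
        if "drug_dict" in config:
            path = Path(config["drug_dict"])
            input_hashes["drug_dict"] = _sha256(path)
            loaded = load_dictionary(path)
            if not isinstance(loaded, DrugDictionary):
                raise ValueError(f"{path} is not a drug dictionary")
            drug_dict = loaded
        if "adr_dict" in config:
            path = Path(config["adr_dict"])
            input_hashes["adr_dict"] = _sha256(path)
            loaded = load_dictionary(path)
            if not isinstance(loaded, ADRDictionary):
                raise ValueError(f"{path} is not an ADR dictionary")
            adr_dict = loaded
        if drug_dict is None and adr_dict is None:
            return reports, drug_dict, adr_dict, 0
        normalized, log = normalize_reports(
            reports,
            drug_dict or DrugDictionary(synonym_map={}),
            adr_dict or ADRDictionary(term_map={}, soc_map={}),
        )
        return normalized, drug_dict, adr_dict, len(log)

    reports, drug_dict, adr_dict, n_unmapped = normalize(reports)
    counts["unmapped_names"] = n_unmapped

    @_stage("filter")
    def filt(reports):
        return filter_reports(reports, _criteria_from_config(config))

    included, excluded = filt(reports)
    counts["reports_included"] = len(included)
    counts["reports_excluded"] = len(excluded)
    if excluded:
        pd.DataFrame(
            [(e.report.report_id, e.reason) for e in excluded],
            columns=["report_id", "reason"],
        ).to_csv(out / "excluded.csv", index=False, lineterminator="\n")

    @_stage("expand")
    def expand(included):
        events = expand_events(included)
        pd.DataFrame(
            [(e.report_id, e.drug, e.adr) for e in events],
            columns=["report_id", "drug", "adr"],
        ).to_csv(out / "events.csv", index=False, lineterminator="\n")
        return events

    events = expand(included)
    counts["events"] = len(events)
    write_reports(included, out / "reports_included.csv")

    @_stage("describe")
    def describe(included, events):
        ddir = out / "describe"
        ddir.mkdir(exist_ok=True)
        sx = sex_summary(included)
        sv = severity_summary(included)
        pd.DataFrame(
            [
                ("n_male", sx.n_male),
                ("n_female", sx.n_female),
                ("n_sex_unknown", sx.n_unknown),
                ("male_female_ratio", sx.ratio if sx.ratio is not None else ""),
                ("n_serious", sv.overall.n_serious),
                ("n_reports", sv.overall.n_total),
                ("percent_serious", sv.overall.percent_serious),
                ("n_new_serious", sv.n_new_serious),
                ("n_new_non_serious", sv.n_new_non_serious),
            ],
            columns=["statistic", "value"],
        ).to_csv(ddir / "summary.csv", index=False, lineterminator="\n")
        rows = severity_by_stratum(included, "drug")
        pd.DataFrame(
            [(b.stratum, b.n_serious, b.n_total, b.percent_serious) for b in rows],
            columns=["drug", "n_serious", "n_total", "percent_serious"],
        ).to_csv(ddir / "severity_by_drug.csv", index=False, lineterminator="\n")
        adr_frequency(events, adr_dict, level="term").to_frame().to_csv(
            ddir / "adr_terms.csv", index=False, lineterminator="\n"
        )
        adr_frequency(events, adr_dict, level="soc").to_frame().to_csv(
            ddir / "adr_soc.csv", index=False, lineterminator="\n"
        )
        route_summary(included).to_frame().to_csv(
            ddir / "routes.csv", index=False, lineterminator="\n"
        )
        oc = outcome_summary(included)
        oc.table.to_frame().to_csv(ddir / "outcomes.csv", index=False, lineterminator="\n")
        oc.deaths.to_csv(ddir / "deaths.csv", index=False, lineterminator="\n")

    describe(included, events)

    @_stage("signals")
    def signals_stage(events):
        signals = mine_signals(events)
        if "labels" in config:
            path = Path(config["labels"])
            input_hashes["labels"] = _sha256(path)
            labels = load_drug_labels(path)
            ddict = (drug_dict or DrugDictionary(synonym_map={})).with_labels(labels)
            signals = off_label_flags(signals, ddict)
        signals_to_frame(signals).to_csv(out / "signals.csv", index=False, lineterminator="\n")
        return signals

    signals = signals_stage(events)
    counts["decs_scored"] = len(signals)
    counts["signals_ror"] = sum(s.flag_ror for s in signals)
    counts["signals_prr"] = sum(s.flag_prr for s in signals)
    counts["signals_mhra"] = sum(s.flag_mhra for s in signals)
    counts["signals_consensus"] = sum(s.consensus for s in signals)
    counts["signals_off_label"] = sum(1 for s in signals if s.off_label is True)

    if sim_cfg is not None and sim_cfg.implants:
        @_stage("recovery")
        def recovery(signals, sim_cfg):
            rec = evaluate_recovery(signals, sim_cfg)
            payload = {
                "per_method": {k: v._asdict() for k, v in rec.per_method.items()},
                "per_implant": {f"{d}|{a}": hit for (d, a), hit in rec.per_implant.items()},
            }
            (out / "recovery.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            return rec

        rec = recovery(signals, sim_cfg)
        counts["implants_detected"] = sum(rec.per_implant.values())
        counts["implants_total"] = len(rec.per_implant)

    manifest = RunManifest(
        input_hashes=input_hashes,
        config=json.loads(json.dumps(config, sort_keys=True, default=str)),
        version=__version__,
        counts=counts,
        started=started,
        finished=dt.datetime.now(dt.timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest
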