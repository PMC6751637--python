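"""End-to-end orchestration: build-dict -> tag -> extract (-> evaluate).

One :class:`RunConfig` (a flat JSON or YAML file mirroring the CLI flags)
drives a reproducible run.  Every stage writes its artifact to the output
directory and the run finishes with a machine-readable JSON report holding
input checksums, parameter values, stage timings and output row counts.
Identical configuration and inputs produce byte-identical association
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

from . import associations as assoc_mod
from . import evaluation as eval_mod
from .lexicon import RefinementConfig, build_dictionary, load_stoplist
from .ontology import Ontology, parse_obo
from .tagger import read_corpus, tag_corpus, write_tagged_jsonl

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one mining run.

    Thresholds default to the standard operating point: NPMI strictly
    above 0.2 and at least 10 sentence co-occurrences.
    """

    pathogen_obo: str = ""
    disease_obo: str = ""
    corpus: str = ""
    out_dir: str = "padminer-run"
    pathogen_roots: list[str] = field(default_factory=list)  # empty -> all roots
    disease_roots: list[str] = field(default_factory=list)
    stoplist: str = ""  # empty -> packaged default
    min_length: int = 3
    npmi_threshold: float = 0.2
    count_threshold: int = 10
    abbreviation_filter: bool = True
    whole_corpus_marginals: bool = False
    reference: str = ""  # optional reference TSV for evaluation
    export_ntriples: bool = False
    seed: int = 0  # used only by `padminer simulate`

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("pathogen_obo", "disease_obo", "corpus"):
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        for name in ("stoplist", "reference"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if self.count_threshold < 1:
            raise ConfigError("count_threshold must be >= 1")
        if self.min_length < 1:
            raise ConfigError("min_length must be >= 1")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``out_dir/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "parameters": asdict(config),
        "inputs": {
            name: _sha256(Path(getattr(config, name)))
            for name in ("pathogen_obo", "disease_obo", "corpus")
        },
        "stages": {},
        "status": "incomplete",
    }

    def stage(name: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            report["stages"][name] = {"error": str(exc)}
            (out / "report.json").write_text(json.dumps(report, indent=1))
            raise StageError(name, exc) from exc
        report["stages"][name] = {"seconds": round(time.perf_counter() - start, 3)}
        return result

    # ---- dictionaries ----------------------------------------------------
    def build_dicts():
        patho_onto = parse_obo(Path(config.pathogen_obo))
        dis_onto = parse_obo(Path(config.disease_obo))
        stop = (
            load_stoplist(config.stoplist)
            if config.stoplist
            else RefinementConfig().stoplist
        )
        refinement = RefinementConfig(min_length=config.min_length, stoplist=stop)
        p_roots = set(config.pathogen_roots) or patho_onto.roots
        d_roots = set(config.disease_roots) or dis_onto.roots
        patho_dict = build_dictionary(
            patho_onto, patho_onto.extract_branch(p_roots), "pathogen", refinement
        )
        dis_dict = build_dictionary(
            dis_onto, dis_onto.extract_branch(d_roots), "disease", refinement
        )
        patho_dict.to_tsv(out / "pathogen_dictionary.tsv")
        dis_dict.to_tsv(out / "disease_dictionary.tsv")
        return patho_onto, dis_onto, patho_dict, dis_dict, p_roots, d_roots

    patho_onto, dis_onto, patho_dict, dis_dict, p_roots, d_roots = stage(
        "build-dict", build_dicts
    )
    report["stages"]["build-dict"].update(
        pathogen_entries=len(patho_dict), disease_entries=len(dis_dict)
    )

    # ---- tagging ---------------------------------------------------------
    def tag():
        docs = read_corpus(config.corpus)
        tagged = list(
            tag_corpus(
                docs, patho_dict, dis_dict,
                apply_abbrev_filter=config.abbreviation_filter,
            )
        )
        write_tagged_jsonl(tagged, out / "tagged.jsonl")
        return tagged

    tagged = stage("tag", tag)
    report["stages"]["tag"].update(
        sentences=len(tagged),
        mentions=sum(len(t.mentions) for t in tagged),
    )

    # ---- extraction ------------------------------------------------------
    def extract():
        counts = assoc_mod.count_cooccurrences(
            tagged, patho_onto, dis_onto,
            pathogen_roots=p_roots, disease_roots=d_roots,
            whole_corpus_marginals=config.whole_corpus_marginals,
        )
        accepted = assoc_mod.extract_associations(
            counts, config.npmi_threshold, config.count_threshold
        )
        assoc_mod.write_associations_tsv(
            accepted, counts, patho_onto, dis_onto, out / "associations.tsv"
        )
        if config.export_ntriples:
            assoc_mod.write_associations_ntriples(
                accepted, out / "associations.nt"
            )
        return counts, accepted

    counts, accepted = stage("extract", extract)
    report["stages"]["extract"].update(
        n_tot=counts.n_tot,
        associations=len(accepted),
        direct=sum(a.direct for a in accepted),
        indirect=sum(not a.direct for a in accepted),
    )

    # ---- optional evaluation --------------------------------------------
    if config.reference:

        def evaluate():
            reference = eval_mod.read_reference_tsv(config.reference)
            extracted = {(a.pathogen_id, a.disease_id) for a in accepted}
            recall, found, missed = eval_mod.recall_against(extracted, reference)
            result = {
                "reference": reference.name,
                "reference_pairs": len(reference.pairs),
                "recall": recall,
                "found": sorted(found),
                "missed": sorted(missed),
            }
            (out / "evaluation.json").write_text(json.dumps(result, indent=1))
            return result

        evaluation = stage("evaluate", evaluate)
        report["stages"]["evaluate"].update(
            recall=evaluation["recall"],
            reference_pairs=evaluation["reference_pairs"],
        )

    report["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "report.json"
    }
    report["status"] = "complete"
    (out / "report.json").write_text(json.dumps(report, indent=1))
    logger.info(
        "run complete: %d associations from %d co-occurrence sentences",
        len(accepted), counts.n_tot,
    )
    return report
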