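"""Readers, writers, configuration and the end-to-end pipeline.

FASTA record ids follow the grammar ``species|individual|locus|allele``
("|" reserved); malformed ids are hard errors, since silent coercion hides
sample mix-ups.  All tables are UTF-8 TSV with one header row; JSON reports
are stable-key-ordered.  Every output carries a provenance header with the
package version, seed and a hash of the configuration, so reruns with
identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import MalformedIdError
from .lifecycle import classify_mechanism, classify_state, map_states
from .orthology import extract_ortholog
from .repeat_core import cryptic_simplicity, decompose
from .threshold_bayes import Observation, compare_models, report_dict


class RecordKey(NamedTuple):
    species: str
    individual: str
    locus: str
    allele: str


def parse_record_id(record_id: str) -> RecordKey:
    parts = record_id.split("|")
    if len(parts) != 4 or not all(parts):
        raise MalformedIdError(
            f"expected species|individual|locus|allele, got {record_id!r}"
        )
    return RecordKey(*parts)


def read_locus_fasta(path) -> dict[RecordKey, str]:
    """Read a multi-record FASTA keyed by parsed record ids."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        key = parse_record_id(rec.id)
        records[key] = str(rec.seq).upper()
    return records


@dataclass
class LocusConfig:
    name: str
    left_flank: str
    right_flank: str
    reference_major: str  # as-written major motif, e.g. "GAA"
    genomic_context: str = "unknown"  # exon / intron / intergenic metadata
    reference_region: str | None = None  # alive reference repeat region


@dataclass
class PipelineConfig:
    loci: list[LocusConfig]
    min_identity: float = 0.80
    min_coverage: float = 1.00
    max_region: int = 2000
    death_threshold: int = 1
    simplicity_cutoff: float = 1.2
    length_tolerance: float = 0.5
    birth_length: int = 5
    motif_len: int = 3
    seed: int = 0
    tree_newick: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        loci = [LocusConfig(**l) for l in data.pop("loci")]
        return cls(loci=loci, **data)


def _provenance(config: PipelineConfig) -> str:
    return (
        f"# msatlife {__version__} seed={config.seed} "
        f"config={config.config_hash()}"
    )


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_observations_tsv(path) -> list[Observation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        Observation(
            repeat_number=int(row.repeat_number),
            dead=int(row.dead),
            species=str(getattr(row, "species", "")),
            locus=str(getattr(row, "locus", "")),
        )
        for row in df.itertuples()
    ]


@dataclass
class PipelineResult:
    extractions: pd.DataFrame
    calls: pd.DataFrame
    tree_map: dict | None
    threshold_report: dict | None
    config_hash: str = ""


def run_pipeline(
    config: PipelineConfig,
    targets: dict[RecordKey, str],
    out_dir=None,
) -> PipelineResult:
    """Extract -> decompose -> classify -> map -> threshold-test.

    *targets* maps record keys to full target sequences (flank + repeat +
    flank, possibly embedded in extra sequence).  Stage failures for a
    record are encoded in its output row; configuration errors raise.
    """
    loci = {l.name: l for l in config.loci}
    ext_rows = []
    call_rows = []
    ref_structures = {
        l.name: decompose(
            l.reference_region
            if l.reference_region
            else l.reference_major * 12,
            config.motif_len,
        )
        for l in config.loci
    }
    for key, target in sorted(targets.items()):
        locus = loci.get(key.locus)
        if locus is None:
            continue
        ext = extract_ortholog(
            locus.left_flank,
            locus.right_flank,
            target,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            max_region=config.max_region,
            locus=locus.name,
            target_id="|".join(key),
        )
        ext_rows.append(
            {
                "species": key.species,
                "individual": key.individual,
                "locus": key.locus,
                "allele": key.allele,
                "accepted": ext.accepted,
                "rejection_reason": ext.rejection_reason or "",
                "identity_left": ext.left_hit.identity if ext.left_hit else float("nan"),
                "identity_right": ext.right_hit.identity if ext.right_hit else float("nan"),
                "region": ext.region,
            }
        )
        if not ext.accepted:
            continue
        structure = decompose(ext.region, config.motif_len)
        call = classify_state(
            structure,
            locus.reference_major,
            threshold=config.death_threshold,
            species=key.species,
            locus=key.locus,
        )
        if call.state == "dead":
            simplicity = None
            if len(ext.region) >= 10:
                simplicity = cryptic_simplicity(
                    ext.region, seed=config.seed
                )
            mech = classify_mechanism(
                ref_structures[locus.name],
                structure,
                simplicity=simplicity,
                threshold=config.death_threshold,
                length_tolerance=config.length_tolerance,
                simplicity_cutoff=config.simplicity_cutoff,
                birth_length=config.birth_length,
            )
            call.mechanism = mech.primary
            call.motif_replacement = mech.motif_replacement
            call.evidence += "; " + mech.evidence
        call_rows.append(
            {
                "species": call.species,
                "locus": call.locus,
                "major_count": call.major_count,
                "state": call.state,
                "mechanism": call.mechanism,
                "motif_replacement": call.motif_replacement,
                "notation": structure.notation(),
                "evidence": call.evidence,
            }
        )

    extractions = pd.DataFrame(ext_rows)
    calls = pd.DataFrame(call_rows)

    tree_map = None
    if config.tree_newick and len(calls):
        consensus_state = (
            calls.groupby("species")["state"]
            .agg(lambda s: "dead" if (s == "dead").all() else "alive")
            .to_dict()
        )
        tm = map_states(config.tree_newick, consensus_state)
        tree_map = {
            "n_transitions": tm.n_transitions,
            "transition_edges": tm.transition_edges,
        }

    threshold_report = None
    if len(calls):
        obs = [
            Observation(
                repeat_number=int(row.major_count),
                dead=int(row.state == "dead"),
                species=row.species,
                locus=row.locus,
            )
            for row in calls.itertuples()
        ]
        low = sum(o.repeat_number <= config.death_threshold for o in obs)
        if 0 < low < len(obs):
            comparison = compare_models(obs, T=config.death_threshold)
            threshold_report = report_dict(comparison, n_obs=len(obs))

    result = PipelineResult(
        extractions=extractions,
        calls=calls,
        tree_map=tree_map,
        threshold_report=threshold_report,
        config_hash=config.config_hash(),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(extractions, out / "extractions.tsv", config)
        write_tsv(calls, out / "lifecycle_calls.tsv", config)
        report = {
            "provenance": {
                "version": __version__,
                "seed": config.seed,
                "config_hash": config.config_hash(),
            },
            "tree_map": tree_map,
            "threshold_report": threshold_report,
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return result
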