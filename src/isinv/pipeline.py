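"""End-to-end orchestration: simulate/load -> annotate -> classify -> events.

The pipeline consumes either a simulation block (a seeded locus panel from
:mod:`isinv.simgen`) or a manifest of aligned FASTA loci with a shared
strain tree, and produces per-strain presence/orientation calls, mechanism
classes, per-locus event reconstructions and a panel summary (how many loci
screened, how many contain at least one inverted element, the fraction).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, locus_io, mechanism, phyloevents, simgen
from .errors import ConfigurationError, IsinvError

log = logging.getLogger("isinv")

INVERTED_CLASSES = {"full_inversion_ab", "internal_inversion_c",
                    "conversion_left_d", "conversion_right_e"}

_SIM_KEYS = {f.name for f in dataclasses.fields(simgen.SimConfig)}


@dataclass
class LocusResult:
    locus_id: str
    calls: list
    mechanisms: list
    reconstruction: object
    has_inverted: bool
    error: str | None = None


@dataclass
class PipelineReport:
    loci: list = field(default_factory=list)
    n_loci: int = 0
    n_inverted_loci: int = 0

    @property
    def fraction_inverted(self) -> float:
        return self.n_inverted_loci / self.n_loci if self.n_loci else 0.0


def locus_from_sim(sim: simgen.LocusSim) -> locus_io.LocusAlignment:
    """View a simulated locus as a LocusAlignment (no file round trip)."""
    aln = locus_io.LocusAlignment(
        locus_id=sim.truth.locus_id,
        strains=list(sim.alignment),
        reference_strain=sim.truth.reference_strain,
        reference_element_interval=tuple(sim.truth.element_interval_alignment),
    )
    aln.validate()
    return aln


def annotate_reference(aln: locus_io.LocusAlignment) -> annotate.AnnotatedElement:
    """Annotate the canonical element on the reference strain (ungapped)."""
    row = aln.row(aln.reference_strain)
    seq, col_to_pos = locus_io.extract_ungapped(
        aln, aln.reference_strain, (1, len(row))
    )
    a, b = aln.reference_element_interval
    return annotate.annotate_element(
        aln.reference_strain, seq, (col_to_pos[a], col_to_pos[b])
    )


def analyse_locus(aln: locus_io.LocusAlignment,
                  tree=None, model=None) -> LocusResult:
    """Run annotation, orientation calling, classification and (optionally)
    event reconstruction on one locus."""
    canonical_ann = annotate_reference(aln)
    if canonical_ann.tirs is None:
        raise ConfigurationError(
            f"{aln.locus_id}: no TIRs detected on the reference element"
        )
    canonical_tirs = canonical_ann.tirs
    calls = locus_io.call_presence_orientation(aln, canonical_ann)

    mechanisms = []
    for call in calls:
        if call.state in ("canonical", "inverted"):
            seq, _ = locus_io.extract_ungapped(
                aln, call.strain_id, aln.reference_element_interval
            )
            observed = annotate.TIRPair.from_element(seq, canonical_tirs.length)
            mechanisms.append(
                mechanism.classify_mechanism(observed, canonical_tirs, call)
            )

    reconstruction = None
    if tree is not None:
        leaf_states = {}
        for call in calls:
            if call.state == "absent":
                leaf_states[call.strain_id] = 0
            elif call.state == "canonical":
                leaf_states[call.strain_id] = 1
            elif call.state == "inverted":
                leaf_states[call.strain_id] = 2
            else:
                leaf_states[call.strain_id] = {0, 1, 2}
        reconstruction = phyloevents.reconstruct_events(tree, leaf_states, model)

    has_inverted = any(m.mechanism_class in INVERTED_CLASSES for m in mechanisms)
    return LocusResult(
        locus_id=aln.locus_id,
        calls=calls,
        mechanisms=mechanisms,
        reconstruction=reconstruction,
        has_inverted=has_inverted,
    )


def _sim_config_from_block(block: dict, seed: int) -> tuple:
    n_loci = int(block.get("n_loci", 1))
    n_inv = int(block.get("n_with_inversion", block.get("n_inverted", 0)))
    scenario = block.get("scenario", "conversion_left_d")
    base_kwargs = {k: v for k, v in block.items() if k in _SIM_KEYS}
    base_kwargs["seed"] = seed
    return n_loci, n_inv, scenario, simgen.SimConfig(**base_kwargs)


def run_pipeline(config: dict, seed: int | None = None,
                 out_dir=None) -> PipelineReport:
    """Run the full pipeline from a config mapping.

    The config either contains a ``simulate`` block (panel parameters for
    :func:`isinv.simgen.simulate_batch`) or a ``loci`` manifest (list of
    ``{locus_id, path, reference_strain, element_interval}``) plus ``tree``
    (newick string or path).  A ``seed`` in the config wins over the ``seed``
    argument, with a warning.  Outputs are written under ``out_dir`` when
    given; the report is also returned.
    """
    cfg_seed = config.get("seed")
    if cfg_seed is not None and seed is not None and cfg_seed != seed:
        log.warning("config seed %s overrides command-line seed %s",
                    cfg_seed, seed)
    seed = cfg_seed if cfg_seed is not None else (seed if seed is not None else 0)

    tree = None
    loci: list = []
    if "simulate" in config:
        n_loci, n_inv, scenario, base = _sim_config_from_block(
            dict(config["simulate"]), seed
        )
        sims = simgen.simulate_batch(n_loci, n_inv, seed, base,
                                     scenario=scenario)
        if sims:
            tree = phyloevents.read_tree(sims[0].truth.tree_newick)
        if out_dir is not None:
            simgen.write_batch(sims, Path(out_dir) / "simulated")
        loci = [locus_from_sim(sim) for sim in sims]
    elif "loci" in config:
        for entry in config["loci"]:
            interval = entry.get("element_interval")
            loci.append(locus_io.read_locus_alignment(
                entry["path"],
                reference_strain=entry.get("reference_strain"),
                element_interval=tuple(interval) if interval else None,
                locus_id=entry.get("locus_id"),
            ))
        if config.get("tree"):
            tree = phyloevents.read_tree(config["tree"])
    else:
        raise ConfigurationError(
            "config needs either a 'simulate' block or a 'loci' manifest"
        )

    report = PipelineReport(n_loci=len(loci))
    for aln in loci:
        try:
            result = analyse_locus(aln, tree=tree)
        except IsinvError as exc:
            log.error("locus %s failed: %s", aln.locus_id, exc)
            result = LocusResult(aln.locus_id, [], [], None, False,
                                 error=str(exc))
        report.loci.append(result)
        if result.has_inverted:
            report.n_inverted_loci += 1

    if out_dir is not None:
        write_report(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def calls_frame(report: PipelineReport) -> pd.DataFrame:
    rows = [
        {"locus": res.locus_id, "strain": c.strain_id, "state": c.state,
         "non_gap_fraction": round(c.non_gap_fraction, 4),
         "orf_strand": c.orf_strand}
        for res in report.loci for c in res.calls
    ]
    return pd.DataFrame(rows, columns=["locus", "strain", "state",
                                       "non_gap_fraction", "orf_strand"])


def mechanisms_frame(report: PipelineReport) -> pd.DataFrame:
    rows = [
        {"locus": res.locus_id, "strain": m.strain_id,
         "class": m.mechanism_class, "left_match": m.left_match,
         "right_match": m.right_match, "evidence": m.evidence}
        for res in report.loci for m in res.mechanisms
    ]
    return pd.DataFrame(rows, columns=["locus", "strain", "class",
                                       "left_match", "right_match", "evidence"])


def events_frame(report: PipelineReport) -> pd.DataFrame:
    rows = [
        {"locus": res.locus_id, "branch": ev["branch"], "event": ev["type"],
         "from": ev["from"], "to": ev["to"]}
        for res in report.loci if res.reconstruction is not None
        for ev in res.reconstruction.events
    ]
    return pd.DataFrame(rows, columns=["locus", "branch", "event",
                                       "from", "to"])


def report_dict(report: PipelineReport) -> dict:
    return {
        "summary": {
            "loci_screened": report.n_loci,
            "loci_with_inversion": report.n_inverted_loci,
            "fraction_inverted": report.fraction_inverted,
        },
        "loci": [
            {
                "locus_id": res.locus_id,
                "has_inverted": res.has_inverted,
                "error": res.error,
                "calls": [dataclasses.asdict(c) for c in res.calls],
                "mechanisms": [dataclasses.asdict(m) for m in res.mechanisms],
                "events": (res.reconstruction.events
                           if res.reconstruction is not None else []),
                "total_cost": (res.reconstruction.total_cost
                               if res.reconstruction is not None else None),
                "n_co_optimal": (res.reconstruction.n_co_optimal
                                 if res.reconstruction is not None else None),
            }
            for res in report.loci
        ],
    }


def write_report(report: PipelineReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls_frame(report).to_csv(out / "calls.tsv", sep="\t", index=False)
    mechanisms_frame(report).to_csv(out / "mechanisms.tsv", sep="\t", index=False)
    events_frame(report).to_csv(out / "events.tsv", sep="\t", index=False)
    summary = pd.DataFrame([{
        "loci_screened": report.n_loci,
        "loci_with_inversion": report.n_inverted_loci,
        "fraction_inverted": round(report.fraction_inverted, 6),
    }])
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report_dict(report), fh, indent=1, sort_keys=True)
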