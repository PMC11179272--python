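"""End-to-end demonstration workflow and MS identification tables.

``run_demo`` reproduces the packaged case study: build the demonstration
knowledge base, mine the L-DOPA -> DHPAA query, verify that the mined oxime
route's putative intermediate equals the held-out DHPAA-oxime structure's
feature vector, check the two delta-transfer identities, and emit an m/z
identification table. The report is a deterministic JSON document: the same
seed and configuration produce byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .chem_core import (
    MolecularFormula,
    featurize,
    monoisotopic_mz,
    nominal_mz,
    parse_structure,
)
from .pathway_miner import Query, mine
from .reaction_kb import DEMO_QUERY, HOLDOUT_COMPOUND, build_demo_kb

__all__ = ["RunConfig", "MrmRecord", "run_demo", "mrm_table", "DemoError"]

logger = logging.getLogger(__name__)

REPORT_FORMAT = "pathminer/1"


class DemoError(RuntimeError):
    """A demo stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    seed: int = 42
    source: str = DEMO_QUERY[0]
    target: str = DEMO_QUERY[1]
    max_steps: int = 3
    threshold: float = 0.7
    iterations: int = 200
    subset_size: int = 20
    c_max: int = 1
    exhaustive: bool = False
    include_decoys: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML or JSON file mirroring the CLI flags."""
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_query(self) -> Query:
        return Query(
            source=self.source,
            target=self.target,
            max_steps=self.max_steps,
            threshold=self.threshold,
            iterations=self.iterations,
            subset_size=self.subset_size,
            c_max=self.c_max,
            seed=self.seed,
            exhaustive=self.exhaustive,
        )


@dataclass(frozen=True)
class MrmRecord:
    """One analyte row: instrument MRM settings vs computed exact mass.

    ``precursor_mz``/``product_mz`` are unit-resolution instrument settings
    (``None`` when no transition is configured); ``computed_mh_exact`` is the
    monoisotopic [M+H]+ computed from the formula.
    """

    analyte: str
    formula: str
    precursor_mz: float | None
    product_mz: float | None
    polarity: str | None
    computed_mh_exact: float

    def __post_init__(self) -> None:
        if self.precursor_mz is not None and self.product_mz is not None:
            if self.precursor_mz <= self.product_mz:
                raise ValueError(
                    f"{self.analyte}: precursor must exceed product for these transitions"
                )


# Fixed quantifier transitions used on the triple-quadrupole instrument; these
# are settings, not computed quantities.
INSTRUMENT_TRANSITIONS: dict[str, tuple[float, float, str]] = {
    "reticuline": (330.10, 192.00, "+"),
    "DHPAA-oxime": (168.10, 151.15, "+"),
}

DEFAULT_ANALYTES: tuple[tuple[str, str], ...] = (
    ("reticuline", "C19H23NO4"),
    ("DHPAA-oxime", "C8H9NO3"),
)


def mrm_table(
    analytes: list[tuple[str, str]] | None = None, out_path: str | Path | None = None
) -> list[MrmRecord]:
    """Build the MRM/identification table for a list of (name, formula) analytes.

    Analytes with a configured instrument transition get it verbatim; every
    analyte additionally gets its computed exact [M+H]+ for cross-checking.
    """
    analytes = list(analytes) if analytes is not None else list(DEFAULT_ANALYTES)
    records = []
    for name, formula in analytes:
        if not formula:
            raise ValueError(f"analyte {name!r} has no formula")
        exact = monoisotopic_mz(MolecularFormula.parse(formula), "+H")
        trans = INSTRUMENT_TRANSITIONS.get(name)
        records.append(
            MrmRecord(
                analyte=name,
                formula=formula,
                precursor_mz=trans[0] if trans else None,
                product_mz=trans[1] if trans else None,
                polarity=trans[2] if trans else None,
                computed_mh_exact=exact,
            )
        )
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("analyte\tformula\tprecursor_mz\tproduct_mz\tpolarity\tcomputed_mh_exact\n")
            for r in records:
                fh.write(
                    f"{r.analyte}\t{r.formula}\t"
                    f"{'' if r.precursor_mz is None else r.precursor_mz}\t"
                    f"{'' if r.product_mz is None else r.product_mz}\t"
                    f"{r.polarity or ''}\t{r.computed_mh_exact}\n"
                )
    return records


def _delta_transfer_checks(kb) -> list[dict]:
    """The two reaction-delta transfer identities behind the predicted route."""
    f = kb.vector
    checks = [
        {
            "name": "aldoxime formation transfers from tyrosine to L-DOPA",
            "holds": f("C00355") + (f("C04353") - f("C00082")) == f("X-DHPAAOX"),
        },
        {
            "name": "oxime-to-carbonyl transfers from acetophenone oxime to DHPAA-oxime",
            "holds": f("X-DHPAAOX") + (f("C07113") - f("CID5464950")) == f("C04043"),
        },
    ]
    return checks


def run_demo(
    seed: int = 42,
    out_dir: str | Path | None = None,
    include_decoys: bool = True,
    config: RunConfig | None = None,
) -> dict:
    """Run the packaged case study end to end and return the report dict.

    Stages: build KB -> mine query -> verify oxime-route intermediate against
    the holdout structure -> delta-transfer checks -> m/z table. Any stage
    failure raises :class:`DemoError` naming the stage.
    """
    config = config or RunConfig(seed=seed, include_decoys=include_decoys)

    try:
        kb = build_demo_kb(config.seed, include_decoys=config.include_decoys)
    except Exception as exc:
        raise DemoError(f"stage build_kb: {exc}") from exc

    try:
        pathways = mine(config.to_query(), kb)
    except Exception as exc:
        raise DemoError(f"stage mine: {exc}") from exc
    if not pathways:
        raise DemoError("stage mine: no pathways found")

    try:
        oxime = [
            p for p in pathways if p.ec_sequence == ("1.14.14.36", "1.2.3.1")
        ]
        holdout_vec = featurize(parse_structure(HOLDOUT_COMPOUND.smiles), kb.schema)
        oxime_check = {
            "route_found": bool(oxime),
            "intermediate_matches_holdout": bool(oxime)
            and oxime[0].steps[0].vector_after == holdout_vec,
            "step_scores": [round(s.step_score, 6) for s in oxime[0].steps]
            if oxime
            else [],
        }
    except Exception as exc:
        raise DemoError(f"stage verify_oxime: {exc}") from exc

    try:
        transfer = _delta_transfer_checks(kb)
    except Exception as exc:
        raise DemoError(f"stage delta_transfer: {exc}") from exc

    try:
        masses = {
            "DHPAA-oxime [M+H]+ exact": monoisotopic_mz("C8H9NO3", "+H"),
            "DHPAA-oxime [M+H]+ nominal": nominal_mz("C8H9NO3", "+H"),
            "reticuline [M+H]+ exact": monoisotopic_mz("C19H23NO4", "+H"),
            "reticuline [M+H]+ nominal": nominal_mz("C19H23NO4", "+H"),
        }
        mrm = [asdict(r) for r in mrm_table()]
    except Exception as exc:
        raise DemoError(f"stage mass_table: {exc}") from exc

    report = {
        "format": REPORT_FORMAT,
        "config": asdict(config),
        "n_pathways": len(pathways),
        "top_pathway": pathways[0].to_dict(),
        "pathways": [p.to_dict() for p in pathways],
        "oxime_route": oxime_check,
        "delta_transfer": transfer,
        "masses": masses,
        "mrm_table": mrm,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kb.save(out / "kb")
        with open(out / "demo_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        mrm_table(out_path=out / "mrm.tsv")
        logger.info("demo report written to %s", out / "demo_report.json")
    return report


def report_summary(report: dict) -> str:
    """Human-readable one-screen summary of a demo report."""
    lines = [
        f"pathways found: {report['n_pathways']}",
        f"top pathway: {report['top_pathway']['n_steps']} steps, "
        f"score {report['top_pathway']['score']:.3f}, "
        f"EC {' -> '.join(s['ec'] for s in report['top_pathway']['steps'])}",
    ]
    ox = report["oxime_route"]
    lines.append(
        "oxime bypass route: "
        + (
            f"found (step scores {ox['step_scores']}), intermediate "
            + (
                "matches holdout DHPAA-oxime"
                if ox["intermediate_matches_holdout"]
                else "DOES NOT match holdout"
            )
            if ox["route_found"]
            else "NOT FOUND"
        )
    )
    for chk in report["delta_transfer"]:
        lines.append(f"delta transfer: {chk['name']}: {'ok' if chk['holds'] else 'FAIL'}")
    for name, val in report["masses"].items():
        lines.append(f"{name}: {val}")
    return "\n".join(lines)
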