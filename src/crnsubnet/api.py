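"""Public API: single-pair and directory-scale subnet discovery.

`find_reference_in_target` answers "is this reference CRN a structurally
identical subnet of this target?" for two models given as files or
in-memory text.  `find_references_in_targets` runs the all-pairs study
over two directories of models, streaming one CSV row per (reference,
target) pair with checkpointing so an interrupted run resumes where it
stopped.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from .core import Network, ParseError, parse_network
from .identity import DiscoveryResult, MappingPair, find_subnets

__all__ = [
    "StudyRow",
    "load_network",
    "find_reference_in_target",
    "find_references_in_targets",
]

logger = logging.getLogger("crnsubnet")

MODEL_EXTENSIONS = {
    ".xml": "sbml",
    ".sbml": "sbml",
    ".ant": "reaction-string",
    ".txt": "reaction-string",
}


@dataclass
class StudyRow:
    """One (reference, target) outcome of a directory study."""

    reference_name: str
    target_name: str
    is_subnet: bool
    truncated: bool
    identity_mode: str
    num_pairs_evaluated: int
    first_mapping: str  # JSON mapping pair, or ""

    FIELDS = (
        "reference_name",
        "target_name",
        "is_subnet",
        "truncated",
        "identity_mode",
        "num_pairs_evaluated",
        "first_mapping",
    )

    @classmethod
    def from_result(cls, result: DiscoveryResult) -> "StudyRow":
        first = ""
        if result.sis_mapping_pairs:
            first = json.dumps(result.sis_mapping_pairs[0].to_dict(), sort_keys=True)
        return cls(
            reference_name=result.reference_name,
            target_name=result.target_name,
            is_subnet=result.is_subnet,
            truncated=result.truncated,
            identity_mode=result.identity_mode,
            num_pairs_evaluated=result.num_pairs_evaluated,
            first_mapping=first,
        )

    def to_record(self) -> dict[str, str]:
        return {
            "reference_name": self.reference_name,
            "target_name": self.target_name,
            "is_subnet": str(self.is_subnet),
            "truncated": str(self.truncated),
            "identity_mode": self.identity_mode,
            "num_pairs_evaluated": str(self.num_pairs_evaluated),
            "first_mapping": self.first_mapping,
        }

    @classmethod
    def from_record(cls, rec: dict[str, str]) -> "StudyRow":
        return cls(
            reference_name=rec["reference_name"],
            target_name=rec["target_name"],
            is_subnet=rec["is_subnet"] == "True",
            truncated=rec["truncated"] == "True",
            identity_mode=rec["identity_mode"],
            num_pairs_evaluated=int(rec["num_pairs_evaluated"]),
            first_mapping=rec["first_mapping"],
        )

    def mapping_pair(self) -> MappingPair | None:
        if not self.first_mapping:
            return None
        d = json.loads(self.first_mapping)
        return MappingPair(species=d["species"], reactions=d["reactions"])


def load_network(source: str | Path, dialect: str | None = None, name: str | None = None) -> Network:
    """Load a model from a file path or from raw text.

    File paths are detected by existence; the dialect comes from the
    extension (.xml/.sbml -> SBML, .ant/.txt -> reaction dialect) unless
    overridden.  Raw text starting with an XML prolog or <sbml> tag is
    parsed as SBML, anything else as the reaction dialect.
    """
    path = Path(source) if not isinstance(source, Path) else source
    try:
        is_file = path.is_file()
    except (OSError, ValueError):
        is_file = False
    if is_file:
        text = path.read_text()
        if dialect is None:
            dialect = MODEL_EXTENSIONS.get(path.suffix.lower())
            if dialect is None:
                dialect = "sbml" if text.lstrip().startswith("<") else "reaction-string"
        return parse_network(text, dialect=dialect, name=name or path.stem)
    text = str(source)
    if dialect is None:
        stripped = text.lstrip()
        dialect = "sbml" if stripped.startswith(("<?xml", "<sbml")) else "reaction-string"
    return parse_network(text, dialect=dialect, name=name or "network")


def find_reference_in_target(
    reference: str | Path | Network,
    target: str | Path | Network,
    max_num_mapping_pair: float = 1e12,
    identity: str = "strong",
    batch_size: int = 1000,
    num_processes: int = 1,
    first_only: bool = False,
    dialect: str | None = None,
) -> DiscoveryResult:
    """Discover sis mapping pairs of ``reference`` inside ``target``.

    The result's ``truncated`` flag indicates that discovery was cut off
    because the number of candidate mapping pairs exceeded
    ``max_num_mapping_pair``.  A reference larger than the target is a
    normal empty result.
    """
    ref = reference if isinstance(reference, Network) else load_network(reference, dialect)
    tgt = target if isinstance(target, Network) else load_network(target, dialect)
    if (
        ref.num_species > tgt.num_species
        or ref.num_reactions > tgt.num_reactions
    ):
        return DiscoveryResult(
            reference_name=ref.name, target_name=tgt.name, identity_mode=identity
        )
    return find_subnets(
        ref,
        tgt,
        mode=identity,
        max_mapping_pairs=max_num_mapping_pair,
        batch_size=batch_size,
        num_processes=num_processes,
        first_only=first_only,
    )


def _model_files(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir() if p.suffix.lower() in MODEL_EXTENSIONS
    )


def _load_directory(directory: Path) -> list[Network]:
    nets = []
    for path in _model_files(directory):
        try:
            nets.append(load_network(path))
        except (ParseError, ValueError) as exc:
            logger.warning("skipping unparseable model %s: %s", path.name, exc)
    return nets


def find_references_in_targets(
    reference_dir: str | Path,
    target_dir: str | Path,
    out_csv: str | Path | None = None,
    max_num_mapping_pair: float = 1e12,
    identity: str = "strong",
    batch_size: int = 1000,
    num_processes: int = 1,
    first_only: bool = True,
) -> list[StudyRow]:
    """All-pairs subnet discovery over two directories of models.

    One row per (reference, target) ordered pair; unparseable models are
    logged and skipped.  With ``out_csv`` the rows are appended as they
    are produced and pairs already present in the file are not recomputed,
    so an interrupted study resumes.
    """
    references = _load_directory(Path(reference_dir))
    targets = _load_directory(Path(target_dir))
    if not references or not targets:
        logger.warning(
            "empty study: %d references, %d targets", len(references), len(targets)
        )

    done: dict[tuple[str, str], StudyRow] = {}
    writer = None
    handle = None
    if out_csv is not None:
        out_path = Path(out_csv)
        if out_path.exists():
            with out_path.open() as fh:
                for rec in csv.DictReader(fh):
                    row = StudyRow.from_record(rec)
                    done[(row.reference_name, row.target_name)] = row
        handle = out_path.open("a", newline="")
        writer = csv.DictWriter(handle, fieldnames=StudyRow.FIELDS)
        if not done and out_path.stat().st_size == 0:
            writer.writeheader()
            handle.flush()

    rows: list[StudyRow] = []
    try:
        for ref in references:
            for tgt in targets:
                key = (ref.name, tgt.name)
                if key in done:
                    rows.append(done[key])
                    continue
                t0 = time.perf_counter()
                result = find_reference_in_target(
                    ref,
                    tgt,
                    max_num_mapping_pair=max_num_mapping_pair,
                    identity=identity,
                    batch_size=batch_size,
                    num_processes=num_processes,
                    first_only=first_only,
                )
                row = StudyRow.from_result(result)
                rows.append(row)
                logger.info(
                    "%s in %s: subnet=%s truncated=%s log10_pairs=%.2f elapsed=%.2fs",
                    ref.name,
                    tgt.name,
                    row.is_subnet,
                    row.truncated,
                    result.log10_pair_estimate,
                    time.perf_counter() - t0,
                )
                if writer is not None:
                    writer.writerow(row.to_record())
                    handle.flush()
    finally:
        if handle is not None:
            handle.close()
    return rows
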