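"""Drug-target curation: affinity filtering and ortholog mapping.

Drug-target interactions are kept when they are biophysical measurements on
human proteins with binding affinity — inhibition constant (Ki),
dissociation constant (Kd), half-maximal effective concentration (EC50), or
half-maximal inhibitory concentration (IC50) — of at most 10 uM (10,000 nM,
inclusive).  Non-human targets are admitted only through an explicit
ortholog table mapping source-species genes to human symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .graphio import DrugTargetSet, normalize_symbol

log = logging.getLogger(__name__)

AFFINITY_TYPES = frozenset({"Ki", "Kd", "EC50", "IC50"})
CUTOFF_NM_DEFAULT = 10_000.0  # 10 uM

#: nM per accepted input unit.
_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "μm": 1e3, "m": 1e9}


@dataclass(frozen=True)
class AffinityRecord:
    """One measured drug-target binding affinity, normalized to nM."""

    drug_id: str
    target_gene: str
    affinity_type: str
    affinity_nM: float
    species: str = "human"

    def __post_init__(self) -> None:
        if self.affinity_type not in AFFINITY_TYPES:
            raise ValueError(f"unknown affinity type {self.affinity_type!r}")
        if not self.affinity_nM > 0:
            raise ValueError(f"non-positive affinity {self.affinity_nM!r}")
        object.__setattr__(self, "target_gene", normalize_symbol(self.target_gene))
        object.__setattr__(self, "species", self.species.strip().lower())


class OrthologMap:
    """Many-to-one source-gene -> human-gene mapping."""

    def __init__(self, pairs: dict[str, str] | None = None) -> None:
        self.pairs = {
            normalize_symbol(src): normalize_symbol(dst)
            for src, dst in (pairs or {}).items()
        }

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, gene: str) -> str | None:
        return self.pairs.get(normalize_symbol(gene))

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        pairs: dict[str, str] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: ortholog row needs 2 columns")
                pairs[fields[0]] = fields[1]
        return cls(pairs)


def map_orthologs(genes, omap: OrthologMap) -> tuple[set[str], list[str]]:
    """Map genes to their human orthologs; returns (mapped set, unmapped list).

    The mapped set is deduplicated (several source genes may share one human
    ortholog); unmapped genes are a reported outcome, not an error.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for gene in sorted({normalize_symbol(g) for g in genes}):
        human = omap.get(gene)
        if human is None:
            unmapped.append(gene)
        else:
            mapped.add(human)
    return mapped, unmapped


def load_affinity_table(path) -> tuple[list[AffinityRecord], list[tuple[int, str]]]:
    """Load a drug-target TSV with columns
    drug_id, target_gene, affinity_type, affinity_value, affinity_unit[, species].

    Affinities are normalized to nM at ingest (accepted units: nM, uM, M).
    Rows with a non-positive or non-numeric affinity, an unknown unit, or an
    unknown affinity type are rejected; each rejection is logged with its line
    number and returned in the second element.
    """
    records: list[AffinityRecord] = []
    rejected: list[tuple[int, str]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("drug_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                rejected.append((lineno, "too few columns"))
                log.warning("%s:%d: rejected (too few columns)", path, lineno)
                continue
            drug_id, target, atype, value, unit = fields[:5]
            species = fields[5] if len(fields) > 5 and fields[5].strip() else "human"
            try:
                magnitude = float(value)
            except ValueError:
                rejected.append((lineno, f"non-numeric affinity {value!r}"))
                log.warning("%s:%d: rejected (non-numeric affinity %r)", path, lineno, value)
                continue
            factor = _UNIT_TO_NM.get(unit.strip().lower())
            if factor is None:
                rejected.append((lineno, f"unknown unit {unit!r}"))
                log.warning("%s:%d: rejected (unknown unit %r)", path, lineno, unit)
                continue
            try:
                records.append(
                    AffinityRecord(drug_id, target, atype.strip(), magnitude * factor, species)
                )
            except ValueError as exc:
                rejected.append((lineno, str(exc)))
                log.warning("%s:%d: rejected (%s)", path, lineno, exc)
    return records, rejected


def filter_targets(
    records: list[AffinityRecord],
    cutoff_nM: float = CUTOFF_NM_DEFAULT,
    ortholog_map: OrthologMap | None = None,
) -> list[DrugTargetSet]:
    """Curate affinity records into one target set per drug.

    A record survives iff its affinity is <= cutoff_nM (inclusive) and its
    target is human — either directly, or via the ortholog map, in which case
    the mapped human symbol is used.  A drug keeps a target if ANY of its
    records for that target passes.  Drugs with zero surviving targets are
    dropped with a log entry.  Idempotent: re-filtering the survivors at the
    same cutoff changes nothing.
    """
    by_drug: dict[str, set[str]] = {}
    dropped_species = 0
    for rec in records:
        if rec.affinity_nM > cutoff_nM:
            continue
        if rec.species == "human":
            human_target = rec.target_gene
        elif ortholog_map is not None:
            human_target = ortholog_map.get(rec.target_gene)
            if human_target is None:
                dropped_species += 1
                continue
        else:
            dropped_species += 1
            continue
        by_drug.setdefault(rec.drug_id, set()).add(human_target)
    if dropped_species:
        log.info("dropped %d non-human records without a human ortholog", dropped_species)
    drugs: list[DrugTargetSet] = []
    for drug_id in sorted(by_drug):
        targets = by_drug[drug_id]
        if targets:
            drugs.append(DrugTargetSet(drug_id, frozenset(targets)))
        else:
            log.info("drug %s dropped: no surviving targets", drug_id)
    return drugs


def write_drug_targets(drugs: list[DrugTargetSet], path) -> None:
    """Write curated target sets as a two-column TSV (drug_id, target_gene)."""
    with Path(path).open("w") as fh:
        fh.write("drug_id\ttarget_gene\n")
        for drug in sorted(drugs, key=lambda d: d.drug_id):
            for target in sorted(drug.targets):
                fh.write(f"{drug.drug_id}\t{target}\n")


def load_drug_targets(path) -> list[DrugTargetSet]:
    """Load curated target sets written by :func:`write_drug_targets`."""
    by_drug: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("drug_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need drug_id and target_gene")
            by_drug.setdefault(fields[0], set()).add(fields[1])
    return [DrugTargetSet(d, frozenset(t)) for d, t in sorted(by_drug.items())]
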