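"""End-to-end comparison of two crystal forms.

Joins the packing, conformational and ADP analyses into one per-residue
table and flags residues whose conformational change co-occurs with a
changed packing environment ("packing-induced" candidates).  The flag rule
is explicit and configurable: side-chain RMSD at or above a threshold
(default 0.5 A) AND either the residue touches the lattice (nearest-mate
distance within the contact cutoff) in exactly one form, or its
contact-partner residue sets differ between the forms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adp import selection_adp_stats
from .compare import ConformationDelta, per_residue_delta
from .errors import EmptySelectionError
from .packing import (
    BurialReport,
    buried_lattice_area,
    contact_counts,
    find_crystal_contacts,
)
from .structure import CrystalStructure
from .symmetry import generate_lattice_neighbors, solvent_content

SCHEMA_VERSION = "1.0"


@dataclass
class ComparisonConfig:
    """Knobs of the two-form comparison; all thresholds must be positive."""

    contact_cutoff: float = 3.5     # A, crystal-contact definition
    probe: float = 1.4              # A, SASA probe radius
    n_points: int = 960             # SASA sphere points per atom
    align_chain: str | None = None  # restrict the global fit
    align_range: tuple[int, int] | None = None
    search_radius: float = 8.0      # A, nearest-mate reporting radius
    flag_sidechain_rmsd: float = 0.5  # A, conformational-change threshold
    altloc: str = "highest"
    include_het: bool = False

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "probe", "search_radius",
                     "flag_sidechain_rmsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_points < 92:
            raise ValueError("n_points must be >= 92")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["align_range"] = list(self.align_range) if self.align_range else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonConfig":
        d = dict(d)
        if d.get("align_range"):
            d["align_range"] = tuple(d["align_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {json.dumps(v)}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ComparisonConfig":
        d = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            d[key.strip()] = json.loads(value.strip())
        return cls.from_dict(d)


@dataclass
class FormSummary:
    """Packing summary of one crystal form."""

    label: str
    contact_counts: dict[str, int]
    buried_area: float
    matthews_vm: float
    solvent_fraction: float
    mean_anisotropy: float | None
    mean_b_iso: float | None


@dataclass
class FormComparisonReport:
    """Joined two-form comparison: packing + conformation + ADP."""

    config: ComparisonConfig
    form_a: FormSummary
    form_b: FormSummary
    global_mainchain_rmsd: float
    global_sidechain_rmsd: float
    per_chain_mainchain_rmsd: dict[str, float]
    per_residue: pd.DataFrame
    flagged: list[tuple[str, int, str]]
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "forms": {
                "a": asdict(self.form_a),
                "b": asdict(self.form_b),
            },
            "global_rmsd": {
                "main_chain": round(self.global_mainchain_rmsd, 3),
                "side_chain": round(self.global_sidechain_rmsd, 3),
                "per_chain_main_chain": {
                    k: round(v, 3) for k, v in self.per_chain_mainchain_rmsd.items()
                },
            },
            "flagged_residues": [list(k) for k in self.flagged],
            "per_residue": json.loads(
                self.per_residue.round(3).to_json(orient="records")),
            "log": self.log,
        }


def _form_summary(structure: CrystalStructure, label: str,
                  config: ComparisonConfig, log: list[str]) -> tuple[
                      FormSummary, dict, dict]:
    contacts = find_crystal_contacts(
        structure, cutoff=config.contact_cutoff,
        include_het=config.include_het, altloc=config.altloc)
    counts = contact_counts(contacts, structure)
    burial = buried_lattice_area(structure, probe=config.probe,
                                 n_points=config.n_points,
                                 include_het=config.include_het,
                                 altloc=config.altloc)
    if burial.notice:
        log.append(f"{label}: {burial.notice}")
    solv = solvent_content(structure)

    mean_a = mean_b = None
    try:
        stats = selection_adp_stats(structure, altloc=config.altloc)
        mean_a = stats["all"].mean_a
        mean_b = stats["all"].mean_b
        if stats["all"].n_missing_u:
            log.append(f"{label}: {stats['all'].n_missing_u} atoms without "
                       "ADP tensors excluded from anisotropy statistics")
    except EmptySelectionError:
        log.append(f"{label}: no ADP tensors; anisotropy columns empty")

    neighborhood = generate_lattice_neighbors(
        structure, config.search_radius, include_het=config.include_het,
        altloc=config.altloc)
    from .packing import nearest_mate_distance
    nearest: dict = {}
    contacts_by_res: dict = {}
    for res in structure.residues:
        if not res.is_polymer and not config.include_het:
            continue
        nearest[res.key] = nearest_mate_distance(
            structure, res.chain_id, res.seq_number, res.insertion_code,
            search_radius=config.search_radius, neighborhood=neighborhood)
        contacts_by_res[res.key] = sorted(
            {c.mate_residue_key for c in contacts if c.ref_residue_key == res.key})
    summary = FormSummary(
        label=label, contact_counts=counts, buried_area=burial.buried_total,
        matthews_vm=solv.matthews_vm, solvent_fraction=solv.solvent_fraction,
        mean_anisotropy=mean_a, mean_b_iso=mean_b)
    return summary, nearest, contacts_by_res


def compare_forms(form_a: CrystalStructure, form_b: CrystalStructure,
                  config: ComparisonConfig | None = None,
                  labels: tuple[str, str] = ("form_a", "form_b"),
                  ) -> FormComparisonReport:
    """Full comparative analysis of two crystal forms of one molecule."""
    config = config or ComparisonConfig()
    log: list[str] = []
    summary_a, nearest_a, partners_a = _form_summary(form_a, labels[0], config, log)
    summary_b, nearest_b, partners_b = _form_summary(form_b, labels[1], config, log)

    delta: ConformationDelta = per_residue_delta(
        form_a, form_b, align_chain=config.align_chain,
        align_range=config.align_range, altloc=config.altloc)

    per_chain: dict[str, float] = {}
    for chain_id in form_a.chain_ids():
        try:
            per_chain[chain_id] = delta.global_rmsd("main_chain", chain=chain_id)
        except ValueError:
            pass

    rows = []
    flagged: list[tuple[str, int, str]] = []
    for key, rd in delta.per_residue.items():
        near_a = nearest_a.get(key)
        near_b = nearest_b.get(key)
        in_contact_a = near_a is not None and near_a <= config.contact_cutoff
        in_contact_b = near_b is not None and near_b <= config.contact_cutoff
        partners_differ = partners_a.get(key, []) != partners_b.get(key, [])
        packing_changed = (in_contact_a != in_contact_b) or partners_differ
        flag = (rd.sidechain_rmsd is not None
                and rd.sidechain_rmsd >= config.flag_sidechain_rmsd
                and packing_changed)
        if flag:
            flagged.append(key)
        if rd.flags:
            log.append(f"{key[0]}/{key[1]}{key[2]}: " + ", ".join(rd.flags))
        chi1 = dict(rd.chi_deltas).get(1)
        chi2 = dict(rd.chi_deltas).get(2)
        rows.append({
            "chain": key[0], "seq": key[1], "icode": key[2],
            "res_name": rd.res_name,
            "mainchain_rmsd": rd.mainchain_rmsd,
            "sidechain_rmsd": rd.sidechain_rmsd,
            "chi1_delta": chi1, "chi2_delta": chi2,
            "max_atom_displacement": (max(rd.atom_displacements.values())
                                      if rd.atom_displacements else None),
            "nearest_mate_a": near_a, "nearest_mate_b": near_b,
            "n_contact_partners_a": len(partners_a.get(key, [])),
            "n_contact_partners_b": len(partners_b.get(key, [])),
            "partners_differ": partners_differ,
            "flagged": flag,
        })
    table = pd.DataFrame(rows)

    return FormComparisonReport(
        config=config,
        form_a=summary_a,
        form_b=summary_b,
        global_mainchain_rmsd=delta.global_rmsd("main_chain"),
        global_sidechain_rmsd=delta.global_rmsd("side_chain"),
        per_chain_mainchain_rmsd=per_chain,
        per_residue=table,
        flagged=flagged,
        log=log,
    )


def render_report(report: FormComparisonReport, out_dir: str | Path,
                  formats: tuple[str, ...] = ("tsv", "json", "markdown"),
                  ) -> dict[str, Path]:
    """Write the report; numeric formatting is fixed (3 decimals) so that
    identical inputs produce byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "tsv" in formats:
        p = out_dir / "per_residue.tsv"
        report.per_residue.round(3).to_csv(p, sep="\t", index=False)
        paths["tsv"] = p
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True,
                                default=_json_default) + "\n")
        paths["json"] = p
    if "markdown" in formats:
        p = out_dir / "report.md"
        p.write_text(_markdown(report))
        paths["markdown"] = p
    return paths


def load_report_dict(path: str | Path) -> dict:
    """Reload a JSON report written by :func:`render_report`."""
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fmt(x, nd=3) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "-"
    return f"{x:.{nd}f}"


def _markdown(report: FormComparisonReport) -> str:
    lines = ["# Crystal-form comparison", ""]
    for s in (report.form_a, report.form_b):
        lines += [
            f"## {s.label}",
            f"- contacts (atom-image pairs): {s.contact_counts['atom_image_pairs']}",
            f"- lattice-buried area: {_fmt(s.buried_area, 1)} A^2",
            f"- Matthews Vm: {_fmt(s.matthews_vm, 2)} A^3/Da; "
            f"solvent fraction: {_fmt(s.solvent_fraction, 3)}",
            f"- mean anisotropy: {_fmt(s.mean_anisotropy)}; "
            f"mean B: {_fmt(s.mean_b_iso, 1)} A^2",
            "",
        ]
    lines += [
        "## Global RMSD",
        f"- main chain: {_fmt(report.global_mainchain_rmsd)} A",
        f"- side chain: {_fmt(report.global_sidechain_rmsd)} A",
        "",
        "## Per-residue",
        "",
        "| chain | res | name | mc RMSD | sc RMSD | dchi1 | dchi2 | flag |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, row in report.per_residue.iterrows():
        lines.append(
            f"| {row['chain']} | {row['seq']}{row['icode']} | {row['res_name']} "
            f"| {_fmt(row['mainchain_rmsd'])} | {_fmt(row['sidechain_rmsd'])} "
            f"| {_fmt(row['chi1_delta'], 1)} | {_fmt(row['chi2_delta'], 1)} "
            f"| {'*' if row['flagged'] else ''} |")
    lines.append("")
    if report.flagged:
        lines.append("Flagged residues (conformational change with changed "
                     "packing environment): "
                     + ", ".join(f"{c}/{s}{i}" for c, s, i in report.flagged))
    else:
        lines.append("No residues flagged.")
    lines.append("")
    return "\n".join(lines)


def config_hash(config: ComparisonConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
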