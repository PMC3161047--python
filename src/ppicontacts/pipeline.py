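"""End-to-end orchestration and relational-table output.

``run_pipeline`` drives one structure through sanitization, chain-pair
enumeration, proximal search, fingerprint classification, solvent
accessibility and environment assignment, and materializes six relational
tables (chains, chain_pairs, residues, residue_pairs, atoms, atom_pairs)
as pandas DataFrames, with TSV mirrors and an embedded SQLite database on
request.  The pipeline is deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .asa import DEFAULT_N_POINTS, interface_area, residue_environments
from .contacts import DEFAULT_RADIUS, enumerate_chain_pairs
from .interactions import FLAG_NAMES, Thresholds, build_fingerprints
from .structure import SanitizeOptions, Structure, sanitize

logger = logging.getLogger(__name__)

TABLE_NAMES = ("chains", "chain_pairs", "residues", "residue_pairs", "atoms", "atom_pairs")


@dataclass
class RunConfig:
    flavour: str = "asu"  # {"asu", "assembly"}
    radius: float = DEFAULT_RADIUS
    thresholds: Thresholds = field(default_factory=Thresholds)
    flip_ambiguous: bool = False
    n_points: int = DEFAULT_N_POINTS
    compute_asa: bool = True
    include_waters: bool = True
    seed: int = 0  # randomized fixture generation only; the pipeline is deterministic

    def describe(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass
class PipelineResult:
    entry_id: str
    tables: dict[str, pd.DataFrame]
    summary: dict[str, int]

    def write_tables(self, outdir: str | Path, sqlite_name: str | None = "tables.sqlite") -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        if sqlite_name:
            with sqlite3.connect(out / sqlite_name) as con:
                for name, df in self.tables.items():
                    if df.columns.empty:
                        continue  # a column-less frame cannot form a table
                    df.to_sql(name, con, if_exists="replace", index=False)


def _res_key(res) -> str:
    return f"{res.chain_id}/{res.res_seq}{res.icode}"


def run_pipeline(s: Structure, cfg: RunConfig | None = None,
                 presanitized: bool = False) -> PipelineResult:
    """Run contact detection and annotation over one (complex) structure."""
    cfg = cfg or RunConfig()
    logger.info("pipeline config: %s", cfg.describe())
    if not presanitized:
        s = sanitize(s, SanitizeOptions(strip_waters=not cfg.include_waters))
    th = cfg.thresholds
    th.proximal = cfg.radius

    chain_rows, atom_rows = [], []
    for ch in s.chains:
        poly = ch.polymer_residues
        if not poly:
            continue
        chain_rows.append(
            dict(entry=s.entry_id, chain=ch.chain_id, n_residues=len(poly),
                 ca_only=ch.is_ca_only)
        )
        for res in poly:
            for atom in res.atoms:
                atom_rows.append(
                    dict(entry=s.entry_id, chain=ch.chain_id, res_seq=res.res_seq,
                         icode=res.icode, res_name=res.res_name, atom=atom.name,
                         element=atom.element, x=round(atom.coord[0], 3),
                         y=round(atom.coord[1], 3), z=round(atom.coord[2], 3))
                )

    pair_rows, atom_pair_rows, residue_pair_rows = [], [], []
    interacting_ids: set[tuple] = set()
    for pair in enumerate_chain_pairs(s):
        classified = build_fingerprints(
            s, pair, th=th, flip_ambiguous=cfg.flip_ambiguous,
            include_waters=cfg.include_waters,
        )
        if not classified:
            continue
        res_pairs: dict[tuple, dict] = {}
        for cp in classified:
            p, fp = cp.pair, cp.fingerprint
            row = dict(
                entry=s.entry_id, chain_i=pair.chain_i, res_i=_res_key(p.res_i),
                res_name_i=p.res_i.res_name, atom_i=p.atom_i.name,
                chain_j=pair.chain_j, res_j=_res_key(p.res_j),
                res_name_j=p.res_j.res_name, atom_j=p.atom_j.name,
                distance=round(p.distance, 3),
            )
            for f in FLAG_NAMES:
                row[f] = getattr(fp, f)
            row["proximal_only"] = fp.proximal_only
            row["hbond_subtype"] = fp.hbond_subtype or ""
            row["aromatic_subtype"] = fp.aromatic_subtype or ""
            atom_pair_rows.append(row)

            rkey = (p.res_i.id, p.res_j.id)
            agg = res_pairs.setdefault(
                rkey,
                dict(entry=s.entry_id, chain_i=pair.chain_i, res_i=_res_key(p.res_i),
                     res_name_i=p.res_i.res_name, chain_j=pair.chain_j,
                     res_j=_res_key(p.res_j), res_name_j=p.res_j.res_name,
                     n_atom_pairs=0, n_contact_atom_pairs=0, min_distance=p.distance),
            )
            agg["n_atom_pairs"] += 1
            agg["min_distance"] = round(min(agg["min_distance"], p.distance), 3)
            if fp.in_contact:
                agg["n_contact_atom_pairs"] += 1
                interacting_ids.add(p.res_i.id)
                interacting_ids.add(p.res_j.id)
        residue_pair_rows.extend(res_pairs.values())

        pair_row = dict(
            entry=s.entry_id, chain_i=pair.chain_i, chain_j=pair.chain_j,
            n_atom_pairs=sum(1 for cp in classified),
            n_contact_atom_pairs=sum(1 for cp in classified if cp.fingerprint.in_contact),
            n_residue_pairs=len(res_pairs),
        )
        if cfg.compute_asa:
            area = interface_area(s, pair, n_points=cfg.n_points)
            pair_row["delta_asa"] = round(area.delta_asa, 1)
        pair_rows.append(pair_row)

    residue_rows = []
    if cfg.compute_asa and s.has_polymer:
        asa_sane = sanitize(s, SanitizeOptions()) if cfg.include_waters else s
        for env in residue_environments(asa_sane, interacting_ids, n_points=cfg.n_points):
            residue_rows.append(
                dict(entry=s.entry_id, chain=env.res.chain_id, res_seq=env.res.res_seq,
                     icode=env.res.icode, res_name=env.res.res_name,
                     interacting=env.interacting,
                     rel_sc_asa=round(env.rel_sc_asa, 2), environment=env.environment)
            )

    tables = {
        "chains": pd.DataFrame(chain_rows),
        "chain_pairs": pd.DataFrame(pair_rows),
        "residues": pd.DataFrame(residue_rows),
        "residue_pairs": pd.DataFrame(residue_pair_rows),
        "atoms": pd.DataFrame(atom_rows),
        "atom_pairs": pd.DataFrame(atom_pair_rows),
    }
    for name in TABLE_NAMES:
        df = tables[name]
        if not df.empty:
            tables[name] = df.sort_values(list(df.columns[:6])).reset_index(drop=True)

    summary = {
        "chains": len(chain_rows),
        "chain_pairs": len(pair_rows),
        "residues": len(residue_rows),
        "residue_pairs": len(residue_pair_rows),
        "atoms": len(atom_rows),
        "atom_pairs": len(atom_pair_rows),
    }
    return PipelineResult(entry_id=s.entry_id, tables=tables, summary=summary)
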