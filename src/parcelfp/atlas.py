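"""Parcel inventory handling.

The atlas table is the frame for every connectivity matrix: its row order
defines the canonical parcel order, its ``is_insular_seed`` flags select the
seed regions whose connectivity fingerprints are analysed, and its hemisphere
labels drive the merge of homologous left/right parcels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_HEMISPHERES = frozenset({"L", "R", "merged"})

ATLAS_COLUMNS = ["parcel_id", "parcel_name", "hemisphere", "macro_region", "is_insular_seed"]


@dataclass(frozen=True)
class AtlasTable:
    """Validated parcel inventory.

    Parameters
    ----------
    table
        One row per parcel with columns ``parcel_id`` (unique key),
        ``parcel_name`` (base name shared by L/R homologues), ``hemisphere``
        (``L``/``R``/``merged``), ``macro_region`` (lobe/system label),
        ``is_insular_seed`` (bool) and optionally ``granularity``
        (agranular/dysgranular/granular). Row order is the canonical parcel
        order for every matrix.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        if t["parcel_id"].duplicated().any():
            dup = t.loc[t["parcel_id"].duplicated(), "parcel_id"].tolist()
            raise ValueError(f"duplicate parcel_id(s): {dup}")
        bad = set(t["hemisphere"]) - VALID_HEMISPHERES
        if bad:
            raise ValueError(f"unknown hemisphere code(s): {sorted(bad)}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- canonical orderings -------------------------------------------------
    @property
    def parcel_ids(self) -> list[str]:
        return self.table["parcel_id"].tolist()

    @property
    def seed_ids(self) -> list[str]:
        m = self.table["is_insular_seed"].astype(bool)
        return self.table.loc[m, "parcel_id"].tolist()

    @property
    def target_ids(self) -> list[str]:
        """Non-seed parcels, in canonical order (the default target axis)."""
        m = ~self.table["is_insular_seed"].astype(bool)
        return self.table.loc[m, "parcel_id"].tolist()

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    def macro_region_of(self, parcel_id: str) -> str:
        row = self.table.loc[self.table["parcel_id"] == parcel_id]
        if row.empty:
            raise KeyError(parcel_id)
        return str(row["macro_region"].iloc[0])

    # -- hemisphere merge ----------------------------------------------------
    def merge_hemispheres(self) -> "AtlasTable":
        """Collapse L/R homologue pairs (shared ``parcel_name``) into merged parcels.

        Raises if any L or R parcel lacks its contralateral homologue. An
        already merged atlas is returned unchanged.
        """
        t = self.table
        if (t["hemisphere"] == "merged").all():
            return self
        groups = t.groupby("parcel_name", sort=False)
        rows = []
        orphans = []
        for name, g in groups:
            hemis = set(g["hemisphere"])
            if hemis == {"merged"}:
                rows.append(g.iloc[0].to_dict())
                continue
            if hemis != {"L", "R"}:
                orphans.append(str(name))
                continue
            first = g.iloc[0].to_dict()
            first["parcel_id"] = str(name)
            first["hemisphere"] = "merged"
            rows.append(first)
        if orphans:
            raise ValueError(f"unpaired hemispheric parcel(s): {orphans}")
        return AtlasTable(pd.DataFrame(rows))


def load_atlas(path) -> AtlasTable:
    """Read an atlas TSV (columns ``parcel_id``, ``parcel_name``, ``hemisphere``,
    ``macro_region``, ``is_insular_seed`` and optional ``granularity``)."""
    t = pd.read_csv(path, sep="\t", dtype={"parcel_id": str, "parcel_name": str})
    if "is_insular_seed" in t.columns:
        t["is_insular_seed"] = (
            t["is_insular_seed"].astype(str).str.lower().isin({"1", "true", "yes"})
        )
    return AtlasTable(t)


def write_atlas(atlas: AtlasTable, path) -> None:
    t = atlas.table.copy()
    t["is_insular_seed"] = t["is_insular_seed"].astype(bool).astype(int)
    t.to_csv(path, sep="\t", index=False)
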