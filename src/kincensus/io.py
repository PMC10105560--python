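"""File formats: pedigree TSV, scenario configs (YAML/JSON), run manifests.

The pedigree format is a PED-like tab-separated table with a header line and
columns id, sex {F,M}, birth_year, death_year (empty = alive at the final
year), mother_id, father_id (0 = unknown).  Two comment lines carry the
metadata a flat table cannot (`# final_year:` and optionally `# species:`),
so write -> read -> write round-trips byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .demography import (ALIVE, Pedigree, SpeciesParams, SPECIES_PRESETS,
                         make_species_params)
from .evaluation import ScenarioConfig

__all__ = ["write_pedigree", "read_pedigree", "load_config", "dump_config",
           "write_manifest"]


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """Write a pedigree as PED-like TSV (see module docstring)."""
    path = Path(path)
    lines = [f"# final_year: {pedigree.final_year}"]
    if pedigree.params is not None and pedigree.params.name in SPECIES_PRESETS:
        lines.append(f"# species: {pedigree.params.name}")
    lines.append("id\tsex\tbirth_year\tdeath_year\tmother_id\tfather_id")
    sex = np.where(pedigree.female, "F", "M")
    for i in range(len(pedigree)):
        death = "" if pedigree.death_year[i] == ALIVE else str(pedigree.death_year[i])
        lines.append(f"{pedigree.ids[i]}\t{sex[i]}\t{pedigree.birth_year[i]}"
                     f"\t{death}\t{pedigree.mother_id[i]}\t{pedigree.father_id[i]}")
    path.write_text("\n".join(lines) + "\n")


def read_pedigree(path: str | Path,
                  params: SpeciesParams | str | None = None,
                  final_year: int | None = None) -> Pedigree:
    """Read a PED-like TSV pedigree.

    `params` (preset name or SpeciesParams) overrides any `# species:`
    comment in the file; `final_year` likewise overrides `# final_year:`.
    Without either source of a final year, the largest year on record is
    used.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    header = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            continue
        if not line.strip():
            continue
        if header is None:
            header = line.split("\t")
            expected = ["id", "sex", "birth_year", "death_year",
                        "mother_id", "father_id"]
            if header != expected:
                raise ValueError(f"bad pedigree header {header!r}; "
                                 f"expected {expected!r}")
            continue
        rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    ids = np.array([int(r[0]) for r in rows], dtype=np.int64)
    female = np.array([r[1] == "F" for r in rows], dtype=bool)
    bad_sex = [r[1] for r in rows if r[1] not in ("F", "M")]
    if bad_sex:
        raise ValueError(f"bad sex codes {sorted(set(bad_sex))}; expected F/M")
    birth = np.array([int(r[2]) for r in rows], dtype=np.int64)
    death = np.array([int(r[3]) if r[3] != "" else ALIVE for r in rows],
                     dtype=np.int64)
    mother = np.array([int(r[4]) for r in rows], dtype=np.int64)
    father = np.array([int(r[5]) for r in rows], dtype=np.int64)

    if params is None and "species" in meta:
        params = meta["species"]
    if isinstance(params, str):
        params = make_species_params(params)
    if final_year is None:
        if "final_year" in meta:
            final_year = int(meta["final_year"])
        else:
            recorded = np.concatenate([birth, death[death != ALIVE]])
            final_year = int(recorded.max(initial=0))
    return Pedigree(ids, female, birth, death, mother, father,
                    final_year=final_year, params=params)


# ---------------------------------------------------------------------------
# scenario configuration

_CONFIG_KEYS = {
    "species", "base_species", "fecundity_grid", "fecundity_sd_grid",
    "sampling_grid", "comparison_fraction", "n_populations", "n_resamples",
    "n_years", "seed",
}
_PARAM_KEYS = {f.name for f in dataclasses.fields(SpeciesParams)}


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML or JSON scenario config with defaults and validation.

    A minimal config like ``{species: wild_boar}`` expands to the full
    defaults (K = 500, 200 years, 30% comparison fraction).  ``base_species``
    may be a preset name or a mapping of SpeciesParams overrides (a
    ``preset`` key selects the starting preset, default red_deer).  Unknown
    or out-of-range fields raise a ValueError naming the offenders.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    if "species" in raw:
        sp = raw["species"]
        species = (sp,) if isinstance(sp, str) else tuple(sp)
        for s in species:
            make_species_params(s)  # raises on unknown preset
        kwargs["species"] = species
        if "base_species" not in raw:
            kwargs["base_species"] = species[0]
    if "base_species" in raw:
        base = raw["base_species"]
        if isinstance(base, dict):
            preset = base.pop("preset", "red_deer")
            bad = set(base) - _PARAM_KEYS
            if bad:
                raise ValueError(f"unknown base_species fields: {sorted(bad)}")
            kwargs["base_species"] = make_species_params(preset).replace(**base)
        else:
            kwargs["base_species"] = make_species_params(base)
    for key in ("fecundity_grid", "fecundity_sd_grid", "sampling_grid"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("comparison_fraction", "n_populations", "n_resamples",
                "n_years", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return ScenarioConfig(**kwargs)  # re-validates ranges


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a config as YAML; load_config(dump_config(c)) == c."""
    d = dataclasses.asdict(config)
    base = d["base_species"]
    if isinstance(base, dict):
        d["base_species"] = {"preset": "red_deer", **base} \
            if base["name"] not in SPECIES_PRESETS else base["name"]
        if isinstance(d["base_species"], dict):
            d["base_species"].pop("name", None)
    d["species"] = list(d["species"])
    for key in ("fecundity_grid", "fecundity_sd_grid", "sampling_grid"):
        d[key] = [float(v) for v in d[key]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_manifest(path: str | Path, *, config=None, seed: int | None = None,
                   stage_seeds: dict | None = None,
                   outputs: dict[str, int] | None = None) -> None:
    """Record everything needed to re-execute a run byte-for-byte.

    `outputs` maps produced file names to their row counts.
    """
    from . import __version__

    doc = {"package": "kincensus", "version": __version__, "seed": seed,
           "stage_seeds": stage_seeds or {}, "outputs": outputs or {}}
    if config is not None:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) \
            else dict(config)
        doc["config"] = json.loads(json.dumps(cfg, default=_jsonable))
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set, np.ndarray)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
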