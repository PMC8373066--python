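"""Seeded synthetic fixtures: parameter tables, a toy FASTA, a TEEM pair.

Everything here is generated, not measured.  The fixtures exist so the
whole pipeline — parameter loading, motif scanning, prediction, TEEM
inference — can run end to end from a single seed with no external data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .energy_tables import ParameterSet
from .teem import DEFAULT_TOTALS, DEFAULT_X0_BULGE, simulate_assay

#: Embedded ΔΔG° of the simulated TEEM bulge (kcal/mol), a typical
#: single-bulge penalty near the middle of the measured range.
FIXTURE_TRUE_DDG = 2.0
#: Reference CX association constant (1/M) for the simulated exchange;
#: of the order of a stable ~20 bp duplex.
FIXTURE_K_REFERENCE = 1e12


def make_toy_fasta(path, seed: int, n_records: int = 2, length: int = 120) -> list:
    """Write a small FASTA with planted homopolymer runs.

    Each record is a seeded random background with a known poly-T and
    poly-G tract inserted, so run scanning has unambiguous truth.
    """
    rng = np.random.default_rng(seed)
    planted = []
    with open(path, "w") as fh:
        for i in range(n_records):
            name = f"toy{i + 1}"
            bg = rng.choice(list("ACGT"), size=length)
            # break accidental long runs in the background
            for j in range(3, length):
                if all(bg[j - k] == bg[j] for k in range(1, 4)):
                    choices = [b for b in "ACGT" if b != bg[j]]
                    bg[j] = rng.choice(choices)
            seq = list(bg)
            for base, run_len, at in (("T", 7 + i, 20), ("G", 5, 70)):
                seq[at - 1] = "A" if base != "A" else "C"
                seq[at : at + run_len] = base * run_len
                seq[at + run_len] = "C" if base != "C" else "A"
                planted.append({"record": name, "base": base,
                                "start": at, "length": run_len})
            fh.write(f">{name}\n")
            s = "".join(seq)
            for j in range(0, len(s), 60):
                fh.write(s[j : j + 60] + "\n")
    return planted


def make_fixtures(seed: int, out_dir) -> dict:
    """Generate the full fixture set and a manifest describing it.

    Writes the synthetic parameter-table trio, a toy FASTA with planted
    runs, a noiseless simulated TEEM pair with embedded true ΔΔG°, its
    YAML config, and ``manifest.json`` listing files and generative
    parameters.  A fixed seed reproduces every byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params_dir = out / "params"
    params = ParameterSet.synthetic(seed)
    written = [str(p.relative_to(out)) for p in params.save_dir(params_dir)]

    fasta = out / "toy.fa"
    planted = make_toy_fasta(fasta, seed + 10)
    written.append("toy.fa")

    pair = simulate_assay(
        true_ddg=FIXTURE_TRUE_DDG,
        k_reference=FIXTURE_K_REFERENCE,
        noise_sd=0.0,
        seed=seed + 20,
    )
    pair.reference.write_csv(out / "teem_reference.csv")
    pair.bulge.write_csv(out / "teem_bulge.csv")
    config = {
        "reference": {k: float(v) for k, v in pair.reference.totals.items()},
        "bulge": {k: float(v) for k, v in pair.bulge.totals.items()},
    }
    with open(out / "assay.yml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    written += ["teem_reference.csv", "teem_bulge.csv", "assay.yml"]

    manifest = {
        "seed": seed,
        "files": sorted(written),
        "parameters": {
            "teem_true_ddg_kcal_mol": FIXTURE_TRUE_DDG,
            "teem_k_reference_per_M": FIXTURE_K_REFERENCE,
            "teem_totals_reference_M": {
                k: float(v) for k, v in DEFAULT_TOTALS.items()
            },
            "teem_x0_bulge_M": DEFAULT_X0_BULGE,
            "planted_runs": planted,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["files"].append("manifest.json")
    return manifest
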