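"""Plain-text key-value configuration.

Schema: one ``key = value`` pair per line, ``#`` comments, blank lines
ignored.  Keys are dotted lower-case paths.  Recognized keys:

    variant                 canonical | dH3H4 | dH2AH2B | dH3pH4p | dH2ApH2Bp
    topology                path to the PDB structure
    trajectories            comma-separated trajectory paths (.dcd or text)
    sampling_interval       ps (default 10)
    window.start_fraction   default 0.5 (latter half)
    window.t0 / window.t1   explicit time range, ps (overrides the fraction)
    cutoff                  contact cutoff, A (default 10)
    n_modes                 PCA modes for the landscape (default 2)
    kde.bandwidth           scott | silverman (default scott)
    output                  output directory
    seed                    integer (stochastic subsampling only)
    chainmap.<ID>           role for chain <ID> (defaults: A-H histones, I-J DNA)
    region.<ROLE>.core      e.g. region.H2A.core = 18-98
    region.<ROLE>.tails     e.g. region.H2A.tails = 1-17,99-128
"""

from __future__ import annotations

from pathlib import Path

from nucdyn.errors import InputError


def parse_kv_file(path: str | Path) -> dict[str, str]:
    items: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        items[key.strip()] = value.strip()
    return items


def write_kv_file(path: str | Path, items: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for key in items:
            fh.write(f"{key} = {items[key]}\n")
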