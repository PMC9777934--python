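"""Multiple sequence alignment via the MAFFT command-line tool."""

from __future__ import annotations

import os
import subprocess
import tempfile


def align(seqs: dict[str, str], protein: bool = False) -> dict[str, str]:
    """Align sequences with MAFFT (``--auto``), preserving input order.

    Single sequences are returned unchanged.  Raises ``RuntimeError`` if
    MAFFT fails.
    """
    if len(seqs) <= 1:
        return dict(seqs)
    with tempfile.TemporaryDirectory() as tmp:
        inpath = os.path.join(tmp, "in.fa")
        with open(inpath, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        cmd = ["mafft", "--auto", "--quiet", "--inputorder"]
        if protein:
            cmd.append("--amino")
        cmd.append(inpath)
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"mafft failed: {proc.stderr[:500]}")
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip()
    return {k: v.upper() for k, v in out.items()}
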