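"""Regenerate the packaged demo archive (examples/demo_archive).

The archive is a synthetic regulon at the simulator defaults, fixed seed 7,
used by the README walkthrough and the end-to-end tests.
"""

from pathlib import Path

from irfootprint.simfix import SimParams, simulate_regulon

ROOT = Path(__file__).resolve().parent.parent

if __name__ == "__main__":
    out = ROOT / "examples" / "demo_archive"
    truth = simulate_regulon(SimParams(seed=7), out)
    print(f"wrote {out}")
    print(f"planted operator: {truth.planted_operator}")
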