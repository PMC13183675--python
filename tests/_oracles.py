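"""Test-side access to the brute-force reference oracles.

The oracles live in ``scripts/_reference.py`` so the acceptance script
can reuse them; they are deliberately naive (exhaustive subset and
ordering enumeration, Floyd-Warshall over plain dictionaries) and share
no code with the package's own algorithms.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

from _reference import (  # noqa: E402,F401
    brute_force_cycles,
    brute_force_metrics,
    floyd_warshall,
    random_graph,
)
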