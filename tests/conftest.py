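import os
import sys

from hypothesis import settings

# allow acceptance tests to reuse the oracle helpers defined in sibling files
sys.path.insert(0, os.path.dirname(__file__))

# fully reproducible property tests
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
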