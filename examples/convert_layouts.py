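"""Show why the event-core layout exists: the duplication it removes.

An occurrence-core archive must copy every sample-level measurement onto
each organism observed in that sample.  Dissolving a small event-core
bundle into that layout multiplies the shared temperature rows; rebuilding
the events collapses them back to one row each.  The printed counts are
the whole argument.
"""

import random
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from helpers import random_option6_instance  # noqa: E402

from obisenv.options import (detect_option, option1_to_option6,
                             option6_to_option1)

bundle = random_option6_instance(random.Random(3))
abiotic = sum(1 for m in bundle.measurements if not m.occurrenceID)
biotic = len(bundle.measurements) - abiotic
print(f"event-core bundle : {len(bundle.events)} events, "
      f"{len(bundle.occurrences)} occurrences, "
      f"{abiotic} event-level + {biotic} biotic rows")

as1 = option6_to_option1(bundle)
print(f"occurrence core   : {len(as1.measurements)} measurement rows "
      f"(each shared row duplicated per organism), "
      f"layout detected: {detect_option(as1)}")

back = option1_to_option6(as1)
collapsed = sum(1 for m in back.measurements if not m.occurrenceID)
print(f"rebuilt event core: {len(back.events)} events, "
      f"{collapsed} event-level rows restored, "
      f"layout detected: {detect_option(back)}")
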