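"""Regenerate the packaged survey-inventory TSV from the compact table.

Maintenance utility: run after editing ``semaplex.fixtures.INVENTORY``.
"""

from pathlib import Path

from semaplex.fixtures import FIXTURE_TSV, inventory_records
from semaplex.io import write_domain_table

if __name__ == "__main__":
    records = inventory_records()
    write_domain_table(records, FIXTURE_TSV)
    size = Path(FIXTURE_TSV).stat().st_size
    print(f"wrote {len(records)} records -> {FIXTURE_TSV} ({size} bytes)")
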