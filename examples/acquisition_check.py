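"""Check a scan's header against expected acquisition parameters.

Writes a small acquisition spec (voxel size, matrix, volume count, TR per
site), compares a phantom's header against it, and produces the
``*_notes.txt`` file describing any deviations. Voxel sizes are compared to
two decimal places, so a header reporting 3.8407 mm against an expected
3.840789 mm is not a deviation.
"""
from pathlib import Path

from epiqc import io, protocol
from epiqc.synthetic import generate_phantom

spec_path = Path("scratch/example_spec.yaml")
spec_path.parent.mkdir(exist_ok=True)
spec_path.write_text(
    "sites:\n"
    "  rest-200:\n"
    "    EPI: {voxel_size: [3, 3, 3.840789], matrix: [20, 20, 12], n_volumes: 150, tr: 2}\n"
    "scans_per_subject: {rest-200: 2}\n"
)
spec = io.read_acquisition_spec(spec_path)

# header rounds the third voxel dimension and is 30 volumes short
series, _, _ = generate_phantom(
    shape=(20, 20, 12, 120), voxel_size=(3.0, 3.0, 3.8407), tr=2.0, seed=0
)
deviations = protocol.check_acquisition(
    series, spec, site="rest-200", observed_scan_count=2
)
notes = io.write_notes(deviations, Path("scratch/sub-201_notes.txt"))
print(f"{len(deviations)} deviation(s) found:  # voxel size matches to 2 d.p.")
print(notes.read_text().rstrip())
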