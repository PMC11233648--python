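"""Simulate the demo session: 3 areas x 20 units, two stimulus types with
distinct planted coupling sets, shared slow rate modulation.

Writes the session tables (spikes/units/trials) and per-stimulus coupling
tables under results/analysis/session/.
"""

import numpy as np

import spikenet as sn
from _common import CONFIG, OUT, STIMULI


def main():
    rng = np.random.default_rng(CONFIG.seed)
    base = sn.make_ground_truth(
        CONFIG.population,
        sn.CouplingConfig(n_couplings=0),
        CONFIG.modulation,
        seed=int(rng.integers(2**31 - 1)),
    )
    sessions = []
    for label in STIMULI:
        couplings = sn.synth.draw_couplings(
            base.units, CONFIG.stimuli[label], int(rng.integers(2**31 - 1))
        )
        truth = sn.GroundTruthCouplings(
            couplings=couplings, units=base.units, modulation=CONFIG.modulation
        )
        sess = sn.simulate_session(
            truth,
            n_trials=CONFIG.n_trials,
            n_bins=CONFIG.n_bins,
            seed=int(rng.integers(2**31 - 1)),
            stimulus=label,
        )
        sessions.append(sess)
        (OUT / "session").mkdir(parents=True, exist_ok=True)
        couplings.to_csv(OUT / "session" / f"couplings_{label}.csv", index=False)
        print(
            f"{label}: {len(couplings)} planted couplings "
            f"({(couplings['sign'] > 0).sum()} positive), "
            f"{sess.n_trials} trials x {sess.n_bins} ms"
        )

    data = sn.SpikeTrainSet(
        spikes=np.concatenate([s.spikes for s in sessions]),
        trial_stimulus=np.concatenate([s.trial_stimulus for s in sessions]),
        units=sessions[0].units,
        bin_ms=CONFIG.bin_ms,
    )
    sn.write_session(data, OUT / "session")
    rates = data.rates_hz()
    print(
        f"session written: {data.n_units} units, mean rate "
        f"{rates.mean():.1f} Hz (range {rates.min():.1f}-{rates.max():.1f})"
    )


if __name__ == "__main__":
    main()
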