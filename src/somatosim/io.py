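"""Serialization of stimuli, spike trains, stimulation trains and
recordings to HDF5 and CSV."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .afferent_sim import PressureStimulus, SpikeTrainSet
from .stim_encoding import StimTrain
from .synthetic_ephys import (GroundTruth, MultichannelRecording,
                              ProbeGeometry)


def save_simulation_h5(path: str | Path, stimulus: PressureStimulus,
                       spikes: SpikeTrainSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        g.create_dataset("samples", data=stimulus.samples)
        g.attrs["time_step"] = stimulus.time_step
        g.attrs["noise_fraction"] = stimulus.noise_fraction
        s = f.create_group("spikes")
        s.attrs["duration"] = spikes.duration
        s.attrs["trial_index"] = spikes.trial_index
        for k, t in enumerate(spikes.spike_times):
            d = s.create_dataset(f"unit_{k}", data=t)
            if spikes.classes:
                d.attrs["afferent_class"] = spikes.classes[k]


def load_simulation_h5(path: str | Path
                       ) -> tuple[PressureStimulus, SpikeTrainSet]:
    with h5py.File(path, "r") as f:
        g = f["stimulus"]
        stimulus = PressureStimulus(float(g.attrs["time_step"]),
                                    g["samples"][:],
                                    float(g.attrs["noise_fraction"]))
        s = f["spikes"]
        keys = sorted((k for k in s if k.startswith("unit_")),
                      key=lambda k: int(k.split("_")[1]))
        trains = [s[k][:] for k in keys]
        classes = [s[k].attrs.get("afferent_class", "") for k in keys]
        spikes = SpikeTrainSet(trains, float(s.attrs["duration"]),
                               int(s.attrs["trial_index"]), classes)
    return stimulus, spikes


def spikes_to_csv(path: str | Path, spikes: SpikeTrainSet) -> None:
    rows = []
    for k, t in enumerate(spikes.spike_times):
        cls = spikes.classes[k] if spikes.classes else ""
        for ts in t:
            rows.append({"unit_id": k, "class": cls, "spike_time_s": ts})
    pd.DataFrame(rows, columns=["unit_id", "class", "spike_time_s"]
                 ).to_csv(path, index=False)


def stim_train_to_csv(path: str | Path, train: StimTrain) -> None:
    pd.DataFrame({"onset_s": train.pulse_onsets,
                  "amplitude_ua": train.amplitude_ua,
                  "pulse_width_us": train.pulse_width_us,
                  "charge_nc": train.charge_per_pulse_nc}
                 ).to_csv(path, index=False)


def stim_train_from_csv(path: str | Path,
                        encoding_label: str = "TONIC") -> StimTrain:
    df = pd.read_csv(path)
    return StimTrain(df["onset_s"].to_numpy(),
                     df["amplitude_ua"].to_numpy(),
                     df["pulse_width_us"].to_numpy(), encoding_label)


def save_recording_h5(path: str | Path, recording: MultichannelRecording,
                      truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=recording.voltages,
                         compression="gzip")
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = recording.sampling_rate
        meta.attrs["n_channels"] = recording.geometry.n_channels
        meta.attrs["layout"] = recording.geometry.layout
        meta.attrs["spacing_um"] = recording.geometry.inter_channel_spacing_um
        meta.create_dataset("trial_events", data=recording.trial_events)
        if truth is not None:
            t = f.create_group("truth")
            t.attrs["drive_label"] = truth.drive_label
            for ch, s in enumerate(truth.spike_times):
                t.create_dataset(f"spikes/channel_{ch}", data=s)
            t.create_dataset("artifacts",
                             data=np.asarray(truth.artifact_windows,
                                             float).reshape(-1, 2))


def load_recording_h5(path: str | Path
                      ) -> tuple[MultichannelRecording, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        meta = f["meta"]
        geom = ProbeGeometry(int(meta.attrs["n_channels"]),
                             str(meta.attrs["layout"]),
                             float(meta.attrs["spacing_um"]))
        rec = MultichannelRecording(float(meta.attrs["sampling_rate"]),
                                    f["voltages"][:], geom,
                                    meta["trial_events"][:])
        truth = None
        if "truth" in f:
            t = f["truth"]
            keys = sorted(t["spikes"], key=lambda k: int(k.split("_")[1]))
            truth = GroundTruth([t["spikes"][k][:] for k in keys],
                                [tuple(w) for w in t["artifacts"][:]],
                                None, str(t.attrs["drive_label"]))
    return rec, truth
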