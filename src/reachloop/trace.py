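"""Time-indexed simulation records and their on-disk form."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net


@dataclass
class ReachTrace:
    """Down-sampled record of one simulation segment.

    Arrays are row-aligned on `time` (seconds of absolute simulation time):
    `activities` (n, 74), `plant` (n, 28) in the `_kernels` state layout,
    `target` (n, 2) hand-space target.  `weights` (m, n_edges) snapshots at
    `weight_time` if weight recording was on.
    """
    time: np.ndarray
    activities: np.ndarray
    plant: np.ndarray
    target: np.ndarray
    weights: np.ndarray | None = None
    weight_time: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- derived views -------------------------------------------------
    @property
    def joint_angles(self):
        return self.plant[:, 0:2]

    @property
    def joint_velocities(self):
        return self.plant[:, 2:4]

    @property
    def tensions(self):
        return self.plant[:, 4:10]

    @property
    def hand(self):
        L1 = self.meta.get("L1", 0.3)
        L2 = self.meta.get("L2", 0.3)
        q1 = self.plant[:, 0]
        q12 = q1 + self.plant[:, 1]
        return np.column_stack([L1 * np.cos(q1) + L2 * np.cos(q12),
                                L1 * np.sin(q1) + L2 * np.sin(q12)])

    @property
    def hand_speed(self):
        v = np.gradient(self.hand, self.time, axis=0)
        return np.hypot(v[:, 0], v[:, 1])

    def pop(self, which):
        """Activities of one population by name, e.g. trace.pop('M')."""
        sl = {"SP": net.SP, "SA": net.SA, "SPA": net.SPA, "M": net.M,
              "A": net.A, "CE": net.CE, "CI": net.CI, "AL": net.AL}[which]
        return self.activities[:, sl]

    def __len__(self):
        return len(self.time)

    @staticmethod
    def concatenate(traces):
        tr = traces[0]
        w = None
        wt = None
        if all(t.weights is not None for t in traces):
            w = np.vstack([t.weights for t in traces])
            wt = np.concatenate([t.weight_time for t in traces])
        return ReachTrace(
            time=np.concatenate([t.time for t in traces]),
            activities=np.vstack([t.activities for t in traces]),
            plant=np.vstack([t.plant for t in traces]),
            target=np.vstack([t.target for t in traces]),
            weights=w, weight_time=wt, meta=dict(tr.meta))

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time}
        for u in range(self.activities.shape[1]):
            cols[f"u{u:02d}"] = self.activities[:, u]
        cols["q1"], cols["q2"] = self.plant[:, 0], self.plant[:, 1]
        cols["qd1"], cols["qd2"] = self.plant[:, 2], self.plant[:, 3]
        hand = self.hand
        cols["hand_x"], cols["hand_y"] = hand[:, 0], hand[:, 1]
        cols["target_x"], cols["target_y"] = self.target[:, 0], self.target[:, 1]
        return pd.DataFrame(cols)

    def save(self, path, fmt="hdf5"):
        """Write the trace (hdf5 or csv) plus a JSON metadata sidecar."""
        path = str(path)
        if fmt == "hdf5":
            import h5py
            with h5py.File(path, "w") as f:
                f.create_dataset("time", data=self.time)
                f.create_dataset("activities", data=self.activities)
                f.create_dataset("plant", data=self.plant)
                f.create_dataset("target", data=self.target)
                if self.weights is not None:
                    f.create_dataset("weights", data=self.weights)
                    f.create_dataset("weight_time", data=self.weight_time)
        elif fmt == "csv":
            self.to_frame().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown trace format {fmt!r}")
        with open(path + ".json", "w") as f:
            json.dump({k: v for k, v in self.meta.items()
                       if isinstance(v, (int, float, str, bool, list))},
                      f, indent=1)

    @staticmethod
    def load(path):
        import h5py
        with h5py.File(str(path), "r") as f:
            kw = {k: f[k][...] for k in
                  ("time", "activities", "plant", "target") if k in f}
            if "weights" in f:
                kw["weights"] = f["weights"][...]
                kw["weight_time"] = f["weight_time"][...]
        try:
            with open(str(path) + ".json") as f:
                meta = json.load(f)
        except FileNotFoundError:
            meta = {}
        return ReachTrace(meta=meta, **kw)
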