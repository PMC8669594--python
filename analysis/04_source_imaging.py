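"""Project MRCP epochs to source space and average into the 24 ROIs.

Noise covariance from the preprocessed rest block, sLORETA operator at
SNR 3, signed ROI means -> sMRCP container.
"""

from graspsource import inverse, io, preprocess

from common import DATA, RESULTS


def main():
    epochs = io.load_epochs(RESULTS / "epochs.h5")
    rest = io.load_recording(DATA / "rest.h5")
    leadfield = io.load_leadfield(DATA / "leadfield.h5")
    cov = inverse.estimate_noise_cov(preprocess.preprocess_rest(rest))
    op = inverse.sloreta_operator(leadfield, cov, snr=3.0)
    smrcp = inverse.apply_inverse(epochs, op)
    io.save_sources(smrcp, RESULTS / "smrcp.h5")
    print(
        f"sMRCP: {smrcp.n_trials} trials x {len(smrcp.roi_labels)} ROIs, "
        f"regularization lambda = {op.lam:.4g}"
    )


if __name__ == "__main__":
    main()
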