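"""Full pipeline: 100 phantoms, 70/30 split, Gaussian-kernel SVM, 10-fold CV.

Prints held-out metrics (sensitivity, both specificity variants, accuracy),
the cross-validation summary, the per-class luminance statistics the
phantoms were calibrated to, and the Welch test separating the classes.
"""

from lumicat import pipeline

report = pipeline.run_pipeline(pipeline.RunConfig(seed=1))

cl = report["class_luminance"]
print(f"training class luminance: healthy {cl['healthy_mean']:.1f} "
      f"+/- {cl['healthy_sd']:.1f} lumen | diseased {cl['diseased_mean']:.1f} "
      f"+/- {cl['diseased_sd']:.1f} lumen")

m = report["metrics"]
print(f"held-out ({report['n_test']} images): accuracy {m['accuracy_pct']:.1f}% | "
      f"sensitivity {m['sensitivity_pct']:.1f}% | "
      f"specificity {m['specificity_standard_pct']:.1f}% "
      f"(TN/(TN+FN) variant {m['specificity_paper_pct']:.1f}%)")

cv = report["cv"]
print(f"10-fold CV on the {report['n_train']} training images: "
      f"{cv['mean_pct']:.1f} +/- {cv['sd_pct']:.1f}%")

t = report["t_test"]
print(f"Welch test healthy vs diseased mean luminance: t={t['t']:.1f}, p={t['p']:.2e}")
print("Across seeds the held-out accuracy averages in the mid-to-high 90s:")
print("the class luminance distributions overlap slightly, so an occasional")
print("low-opacity cataract resembles a healthy lens.")
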