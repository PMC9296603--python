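# gestaltmask

Perceptual (gestalt) contour extraction for grayscale imagery, built around an
EM-driven deformable, rotatable sampling mask.

Low-level edge detectors mark every strong intensity discontinuity, but a
human looking at the same scene perceives only the *object contours* — edges
that align with their neighbours into smooth boundaries, while texture and
noise responses are discounted. `gestaltmask` screens the output of a standard
detector down to that perceptual subset. It is aimed at anyone who needs
clean, single-pixel-wide object boundaries from photographic or biological
imagery (microscopy, specimen photography, natural scenes) without training
data: the screening is fully unsupervised and has essentially two knobs.

## The method

For a candidate edge pixel $(x,y)$ (from Canny, or any detector), a
rectangular mask of constant area $B_n = L \times W$ is centred on it
(initially $7\times7$). Each EM iteration samples the gradient-orientation
feature map under the mask footprint, histograms the orientations into $B_n$
bins, and evaluates the gestalt likelihood

$$p = \frac{h_T}{h_{max}}\;\cdot\;\frac{\mathcal{H}_{max} - \mathcal{H}}{\mathcal{H}_{max}},
\qquad \mathcal{H} = -\sum_i h_i \log h_i,\quad \mathcal{H}_{max} = -\log\tfrac{1}{B_n},$$

the product of a *belief* term (how well the target's own bin $h_T$ agrees
with the dominant bin $h_{max}$) and the *directivity* (the normalized entropy
deficit — how concentrated the local orientations are). The mask width then
snaps to $W = \lfloor r(1-p)\rfloor$ or $\lceil r(1-p)\rceil$ with
$r=\sqrt{B_n}$ (floor when $p$ rose, ceiling when it fell), the length follows
as $L = B_n/W$, and the long axis rotates onto the histogram's maximal bin —
the local principal direction. A confident contour elongates the mask along
itself ($W \to 1$); an isotropic neighbourhood keeps it square. The squared
residual $[W - r(1-p)]^2$ is a Lyapunov objective whose first-order change is
never positive, and iteration stops when $W$ stabilizes.

A mirrored mask runs on the complement feature map (weak-gradient
orientations) and produces the non-gestalt likelihood $\bar p$. With the
normalized log gradient magnitude $g^N$ as prior, the Bayes posterior

$$p(\Omega\mid x,y) = \frac{p^c\, g^N}{p^c\, g^N + \bar p^{\,c}\,(1-g^N)}$$

is thresholded at $k$ (default 0.5, the minimum-error cut) to accept or remove
the candidate. Footprint pixels sharing the accepted target's orientation bin
are co-labeled gestalt directly — the continuity-law shortcut. Evaluation
utilities implement distance-tolerant matching, Pratt's figure of merit,
EQ/MQ (with the F1 form), and the screening rate
$sR = \frac{n(CEP) - n(DT)}{n(CEP)}\%$.

## Worked example

The likelihood on the four canonical converged-mask contents (18 sampled
orientations split 15/3 between two bins, Bn = 49):

```python
from gestaltmask import fig6_fixture, orientation_histogram, gestalt_likelihood

for case in "abcd":
    theta, footprint, target, bn = fig6_fixture(case)
    hist = orientation_histogram(theta, footprint, bn, theta[target])
    print(case, round(gestalt_likelihood(hist, bn), 3))
```

```
a 0.0      # orientations exactly uniform: no principal direction
b 0.177    # target in the 3-count bin: belief 0.2 discounts the directivity
c 0.884    # target in the 15-count bin: full belief, high likelihood
d 1.0      # every sample shares the target's bin
```

End-to-end on a generated test scene (high-contrast square with a textured
interior, corrupted by 10% impulse noise):

```python
from gestaltmask import noisy_square_scene, extract_contours, PipelineConfig, evaluate

scene = noisy_square_scene(seed=0)
result = extract_contours(scene.image, PipelineConfig(prefilter="median"))
print(result.stats)
print(evaluate(result.gestalt_map, scene.gt_contours, d0=1, n_cep=len(result.cep)))
```

```
PipelineStats(processed=66, co_labeled=157, accepted=55, rejected=11)
EvalReport(d0=1, TP=188, FP=24, FN=0, EQ=0.8867924528301887, MQ=0.8867924528301887,
           MQ_f1=0.94, FoM=0.6938431970374188, sR=4.932735426008969)
```

The eleven rejected candidates are texture responses (a 4.9% screening rate);
no ground-truth contour pixel is lost (FN = 0), so map quality after screening
is above the raw candidate set's. The same run is available from
the shell:

```sh
gestaltmask extract scene.png --prefilter median --out contours.png
```

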