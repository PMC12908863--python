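# Default wavelength-dependent effective photon pathlengths X(lambda), in cm,
# for mouse dorsal cortex imaged through a thinned-skull window.
# These are literature-typical order-of-magnitude defaults: the effective
# pathlength is experiment-specific (skull preparation, tissue optics) and
# MUST be confirmed or overridden per setup.
470: 0.056
505: 0.057
530: 0.057
560: 0.065
590: 0.068
625: 0.21
656: 0.30
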