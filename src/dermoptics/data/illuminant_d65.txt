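# D65-like daylight spectral power distribution (relative, 100 at 560 nm)
# smooth resampling of coarse anchor values; idealized, not the CIE table
# columns: wavelength_nm  relative_power
450 117
455 117.7
460 117.8
465 116.35
470 114.9
475 115.4
480 115.9
485 112.35
490 108.8
495 109.1
500 109.4
505 108.861
510 107.8
515 106.039
520 104.8
525 106.25
530 107.7
535 106.139
540 104.4
545 104.202
550 104
555 102.39
560 100
565 97.7796
570 96.3
575 96.0567
580 95.8
585 92.1332
590 88.7
595 89.35
600 90
605 89.8826
610 89.6
615 88.8991
620 87.7
625 85.1683
630 83.3
635 83.5
640 83.7
645 81.85
650 80
655 80.0543
660 80.2
665 81.2957
670 82.3
675 80.9825
680 78.3
685 73.3175
690 69.7
695 70.3712
700 71.6
705 73.2288
710 74.3
715 67.95
720 61.6
725 64.9507
730 69.9
735 73.2993
740 75.1
745 71.8312
750 63.6
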