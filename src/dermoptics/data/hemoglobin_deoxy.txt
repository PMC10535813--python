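# deoxygenated hemoglobin whole-blood absorption spectrum (idealized)
# units: 1/mm per unit blood volume fraction
# synthetic smooth curve anchored at representative literature magnitudes;
# reproduces the qualitative band structure, not a measured table
# columns: wavelength_nm  extinction_per_mm
450 29.8
455 21.3056
460 15.5
465 12.0198
470 10
475 9.08713
480 8.7
485 8.964
490 9.5
495 10.2416
500 11.2
505 12.2689
510 13.5
515 14.8969
520 16.5
525 18.4286
530 20.5
535 22.5973
540 24.5
545 26.2354
550 27.8241
555 28.6717
560 28.1702
565 26.3877
570 24
575 20.0539
580 16.6256
585 13.8494
590 11.5
595 9.49225
600 7.9
605 6.65113
610 5.55277
615 4.65302
620 4
625 3.51918
630 3.10176
635 2.74442
640 2.44388
645 2.19684
650 2
655 1.84164
660 1.70814
665 1.59337
670 1.49118
675 1.39544
680 1.3
685 1.20547
690 1.11692
695 1.03491
700 0.96
705 0.883915
710 0.803411
715 0.726628
720 0.661705
725 0.616783
730 0.6
735 0.609094
740 0.63675
745 0.683531
750 0.75
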