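# oxygenated hemoglobin whole-blood absorption spectrum (idealized)
# units: 1/mm per unit blood volume fraction
# synthetic smooth curve anchored at representative literature magnitudes;
# reproduces the qualitative band structure, not a measured table
# columns: wavelength_nm  extinction_per_mm
450 33.7
455 28.6588
460 24.3234
465 20.7513
470 18
475 16.0073
480 14.5
485 13.2456
490 12.3
495 11.5667
500 11.2
505 11.6233
510 12.5
515 13.7415
520 15.5
525 18.0009
530 21
535 24.8583
540 28.2002
545 27.8528
550 25
555 20.5533
560 17.5
565 20.1256
570 24
575 26.529
580 24.1854
585 15
590 7.5
595 3.65889
600 1.72
605 1.22765
610 0.893792
615 0.680534
620 0.55
625 0.455406
630 0.375254
635 0.309589
640 0.25846
645 0.221915
650 0.2
655 0.186169
660 0.174074
665 0.164062
670 0.156481
675 0.151678
680 0.15
685 0.150839
690 0.153071
695 0.156267
700 0.16
705 0.165046
710 0.17239
715 0.181917
720 0.19351
725 0.207055
730 0.222435
735 0.239536
740 0.25824
745 0.278434
750 0.3
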