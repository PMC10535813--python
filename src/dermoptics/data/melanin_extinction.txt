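# eumelanin effective extinction spectrum
# units: 1/mm per unit melanosome volume fraction
# power-law approximation mu_a = 51.9 * (lambda/500 nm)^-3.33
# columns: wavelength_nm  extinction_per_mm
450 73.7123
455 71.0493
460 68.51
465 66.0875
470 63.7752
475 61.567
480 59.4572
485 57.4404
490 55.5117
495 53.6664
500 51.9
505 50.2085
510 48.588
515 47.0348
520 45.5456
525 44.1171
530 42.7463
535 41.4304
540 40.1667
545 38.9527
550 37.7859
555 36.6642
560 35.5854
565 34.5475
570 33.5486
575 32.5869
580 31.6608
585 30.7686
590 29.9089
595 29.0801
600 28.2809
605 27.5101
610 26.7663
615 26.0485
620 25.3556
625 24.6864
630 24.0399
635 23.4154
640 22.8117
645 22.2282
650 21.6639
655 21.1181
660 20.59
665 20.079
670 19.5843
675 19.1054
680 18.6416
685 18.1923
690 17.757
695 17.3352
700 16.9263
705 16.5298
710 16.1453
715 15.7724
720 15.4106
725 15.0595
730 14.7188
735 14.388
740 14.0668
745 13.7549
750 13.4519
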