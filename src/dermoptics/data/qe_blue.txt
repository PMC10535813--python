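# idealized camera quantum efficiency, blue channel
# Gaussian response centered at 465 nm (sigma 35 nm), relative units
# columns: wavelength_nm  relative_response
450 0.912254
455 0.960005
460 0.989848
465 1
470 0.989848
475 0.960005
480 0.912254
485 0.849366
490 0.774837
495 0.692569
500 0.606531
505 0.52045
510 0.437565
515 0.360448
520 0.290924
525 0.230066
530 0.178264
535 0.135335
540 0.100669
545 0.0733697
550 0.0523931
555 0.036658
560 0.0251305
565 0.0168799
570 0.011109
575 0.00716336
580 0.00452581
585 0.00280164
590 0.00169928
595 0.00100984
600 0.000588005
605 0.000335463
610 0.000187519
615 0.000102703
620 5.51131e-05
625 2.89778e-05
630 1.49284e-05
635 7.53525e-06
640 3.72665e-06
645 1.80583e-06
650 8.57377e-07
655 3.98845e-07
660 1.81791e-07
665 8.11854e-08
670 3.55239e-08
675 1.523e-08
680 6.39757e-09
685 2.63311e-09
690 1.06184e-09
695 4.19551e-10
700 1.62423e-10
705 6.16096e-11
710 2.28973e-11
715 8.33795e-12
720 2.97488e-12
725 1.03996e-12
730 3.56207e-13
735 1.19543e-13
740 3.93081e-14
745 1.26642e-14
750 3.99768e-15
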