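# idealized camera quantum efficiency, green channel
# Gaussian response centered at 535 nm (sigma 40 nm), relative units
# columns: wavelength_nm  relative_response
450 0.104579
455 0.135335
460 0.172422
465 0.216265
470 0.267052
475 0.324652
480 0.388558
485 0.457833
490 0.531096
495 0.606531
500 0.681941
505 0.75484
510 0.822578
515 0.882497
520 0.932102
525 0.969233
530 0.992218
535 1
540 0.992218
545 0.969233
550 0.932102
555 0.882497
560 0.822578
565 0.75484
570 0.681941
575 0.606531
580 0.531096
585 0.457833
590 0.388558
595 0.324652
600 0.267052
605 0.216265
610 0.172422
615 0.135335
620 0.104579
625 0.0795595
630 0.0595873
635 0.0439369
640 0.0318948
645 0.0227942
650 0.0160377
655 0.011109
660 0.00757568
665 0.00508607
670 0.00336169
675 0.00218749
680 0.00140136
685 0.000883826
690 0.00054878
695 0.000335463
700 0.000201885
705 0.000119613
710 6.97696e-05
715 4.00653e-05
720 2.26509e-05
725 1.26071e-05
730 6.90812e-06
735 3.72665e-06
740 1.97921e-06
745 1.03485e-06
750 5.32697e-07
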